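"""End-to-end orchestration: simulate -> prep -> embed -> fit -> metrics/spectra -> PLS.

A run is driven by a :class:`PipelineConfig` (loadable from YAML), executes its
enabled stages in dependency order into a run directory, and writes a manifest
recording parameters, per-stage seeds (derived from one master seed) and
content digests of every artifact, so identical configs reproduce identical
digests. :func:`report` renders a completed run as a plain-text summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import embedding, hmm, io, metrics, pls, spectra
from .preprocess import ParcelRecording, standardize
from .synthetic import (
    CohortConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_recording,
    simulate_state_chain,
)

logger = logging.getLogger("brainstates")

STAGES = ["simulate", "prep", "embed", "fit", "metrics", "spectra", "pls"]

# upstream artifact each stage needs, and the stage that makes it
_REQUIRES = {
    "prep": [("recordings.h5", "simulate")],
    "embed": [("prepped.h5", "prep")],
    "fit": [("prepped.h5", "prep")],
    "metrics": [("model.h5", "fit"), ("prepped.h5", "prep")],
    "spectra": [("model.h5", "fit"), ("recordings.h5", "simulate"), ("prepped.h5", "prep")],
    "pls": [("metrics.csv", "metrics"), ("cohort.csv", "simulate")],
}


@dataclass
class PipelineConfig:
    """All stage parameters plus stage toggles and a master seed."""

    out_dir: str = "run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    # simulate
    n_subjects: int = 12
    n_parcels: int = 12
    n_states: int = 4
    sampling_rate: float = 250.0
    duration: float = 30.0
    noise_sd: float = 1.0
    # prep
    band: tuple[float, float] = (1.0, 45.0)
    filter_order: int = 5
    notch_freqs: list[float] = field(default_factory=list)
    # embed
    n_lags: int = 15
    pca_components: int | None = None
    # fit
    K: int | None = None  # default: n_states
    n_restarts: int = 3
    max_iter: int = 30
    tol: float = 1e-3
    # spectra
    window: float = 2.0
    n_tapers: int = 4
    fmin: float = 1.0
    fmax: float = 45.0
    n_bands: int = 4
    top_n_parcels: int = 5
    # pls
    n_perm: int = 500
    n_boot: int = 200
    knot: float = 55.0
    effect_size: float = 2.0
    cohort_noise_sd: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed (stable, < 2**31)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(out: Path, stage: str, enabled: list[str]) -> None:
    for artifact, maker in _REQUIRES.get(stage, []):
        if not (out / artifact).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs {artifact}, which is missing: "
                f"enable stage '{maker}' or provide the file"
            )


def run(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        "artifacts": {},
    }
    K = config.K or config.n_states

    if "simulate" in config.stages:
        logger.info("simulate: %d subjects", config.n_subjects)
        seed = config.stage_seed("simulate")
        sim = SimulationConfig(
            n_subjects=config.n_subjects,
            n_parcels=config.n_parcels,
            n_states=config.n_states,
            sampling_rate=config.sampling_rate,
            duration=config.duration,
            noise_sd=config.noise_sd,
            seed=seed,
        )
        recs, paths = [], []
        for s in range(config.n_subjects):
            p = simulate_state_chain(sim, seed=seed + 7 * s + 1)
            recs.append(simulate_recording(p, sim, subject_id=f"sub-{s:04d}", seed=seed + 7 * s + 2))
            paths.append(p)
        io.write_recordings(out / "recordings.h5", recs, seed=seed)
        np.save(out / "true_paths.npy", np.array(paths))
        cohort_cfg = CohortConfig(
            n_subjects=config.n_subjects,
            knot=config.knot,
            salience_brain=np.eye(2, 4 * config.n_states),
            effect_size=config.effect_size,
            noise_sd=config.cohort_noise_sd,
            seed=seed + 99,
        )
        # placeholder brain block; the PLS stage rebuilds features from metrics
        cohort, truth, _ = simulate_cohort(
            np.zeros((config.n_subjects, 4 * config.n_states)), cohort_cfg
        )
        cohort.to_csv(out / "cohort.csv", index=False)
        io.write_ground_truth(out / "ground_truth.json", truth)

    if "prep" in config.stages:
        _require(out, "prep", config.stages)
        from .preprocess import bandpass

        recs = io.read_recordings(out / "recordings.h5")
        prepped = []
        for rec in recs:
            r = bandpass(rec, *config.band, order=config.filter_order)
            if config.notch_freqs:
                from .preprocess import notch

                r = notch(r, config.notch_freqs)
            prepped.append(standardize(r))
        io.write_recordings(out / "prepped.h5", prepped)

    if "embed" in config.stages or "fit" in config.stages:
        _require(out, "embed", config.stages)
        recs = io.read_recordings(out / "prepped.h5")
        embedded = [embedding.embed(r, config.n_lags) for r in recs]
        reduced = embedding.pca_reduce(embedded, config.pca_components)

    if "fit" in config.stages:
        logger.info("fit: K=%d", K)
        model = hmm.fit(
            [e.data.T for e in reduced],
            K=K,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=config.stage_seed("fit"),
        )
        io.write_model(out / "model.h5", model)

    if "metrics" in config.stages or "spectra" in config.stages:
        _require(out, "metrics", config.stages)
        model = io.read_model(out / "model.h5")
        recs = io.read_recordings(out / "prepped.h5")
        embedded = [embedding.embed(r, config.n_lags) for r in recs]
        reduced = embedding.pca_reduce(embedded, config.pca_components)
        stcs = [hmm.posterior(model, e.data.T, subject_id=e.subject_id) for e in reduced]

    if "metrics" in config.stages:
        mlist = [
            metrics.state_metrics(s.viterbi_path, K, config.sampling_rate, s.subject_id)
            for s in stcs
        ]
        rows = []
        for m in mlist:
            row: dict = {"subject": m.subject_id}
            for k in range(K):
                row.update(
                    {
                        f"FO_{k}": m.fractional_occupancy[k],
                        f"LT_{k}": m.mean_lifetime[k],
                        f"INT_{k}": m.mean_interval[k],
                        f"SR_{k}": m.switching_rate[k],
                    }
                )
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        np.save(out / "transitions.npy", np.stack([m.transition for m in mlist]))

    if "spectra" in config.stages:
        _require(out, "spectra", config.stages)
        raw = io.read_recordings(out / "recordings.h5")
        half = config.n_lags // 2
        trimmed, aligned = [], []
        for rec, stc in zip(raw, stcs):
            trimmed.append(
                ParcelRecording(rec.subject_id, rec.data[:, half:-half], rec.sampling_rate)
            )
            aligned.append(stc)
        ss = spectra.group_state_spectra(
            trimmed,
            aligned,
            window=config.window,
            n_tapers=config.n_tapers,
            fmin=config.fmin,
            fmax=config.fmax,
        )
        decomps = [
            spectra.nmf_bands(ss, k, n_bands=config.n_bands, seed=config.stage_seed("spectra"))
            for k in range(K)
        ]
        assignment = spectra.assign_bands(ss, decomps)
        maps = {}
        for k in range(K):
            prof = decomps[k].band_profiles[assignment[k]]
            maps[k] = spectra.band_power_map(ss, prof, departure=True)[k]
        power_map = np.stack([maps[k] for k in range(K)])
        tops = np.stack(
            [spectra.top_parcels(power_map, k, n=config.top_n_parcels) for k in range(K)]
        )
        np.save(out / "psd.npy", ss.psd)
        np.save(out / "psd_freqs.npy", ss.frequencies)
        np.save(out / "power_map.npy", power_map)
        np.save(out / "top_parcels.npy", tops)
        pd.DataFrame({"state": np.arange(K), "band": assignment}).to_csv(
            out / "band_assignment.csv", index=False
        )

    if "pls" in config.stages:
        _require(out, "pls", config.stages)
        mtab = pd.read_csv(out / "metrics.csv")
        cohort = pd.read_csv(out / "cohort.csv")
        truth = io.read_ground_truth(out / "ground_truth.json")
        feat_cols = [c for c in mtab.columns if c != "subject"]
        X = mtab[feat_cols].to_numpy(dtype=float)
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
        # plant the cohort's latent coupling into the measured features so the
        # synthetic run exercises a real brain-behavior covariance
        latent = np.asarray(truth["latent"], dtype=float)
        sb = truth.get("salience_brain")
        if sb is not None:
            sb = np.asarray(sb, dtype=float)[:, : X.shape[1]]
            norms = np.linalg.norm(sb, axis=1, keepdims=True)
            sb = sb / np.where(norms == 0, 1.0, norms)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X = X + float(truth.get("effect_size", 1.0)) * (latent @ sb) * sd
        drop = X.std(axis=0) == 0
        X = X[:, ~drop]
        feat_cols = [c for c, d in zip(feat_cols, drop) if not d]
        Y, y_names = pls.prepare_cognitive_block(cohort, knot=config.knot)
        res = pls.pls_svd(X, Y, x_columns=feat_cols, y_columns=y_names)
        res.perm_p = pls.permutation_test(
            X, Y, n_perm=config.n_perm, seed=config.stage_seed("pls"), result=res
        )
        res = pls.bootstrap_bsr(
            X, Y, n_boot=config.n_boot, seed=config.stage_seed("pls") + 1, result=res
        )
        summary = {
            "singular_values": res.singular_values,
            "explained_fraction": res.explained_fraction,
            "perm_p": res.perm_p,
            "perm_p_fdr": pls.fdr_adjust(res.perm_p),
            "y_columns": y_names,
            "x_columns": feat_cols,
        }
        io.write_ground_truth(out / "pls_summary.json", summary)
        pd.DataFrame(res.bsr_cognitive, index=y_names).to_csv(out / "bsr_cognitive.csv")
        pd.DataFrame(res.bsr_brain, index=feat_cols).to_csv(out / "bsr_brain.csv")

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["artifacts"][p.name] = _digest(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a (possibly partial) run directory."""
    out = Path(run_dir)
    lines = [f"brainstates run report: {out}"]
    warnings_: list[str] = []

    mpath = out / "metrics.csv"
    if mpath.exists():
        m = pd.read_csv(mpath)
        lines.append("\n== temporal metrics (group means) ==")
        means = m.drop(columns=["subject"]).mean()
        for metric in ("FO", "LT", "INT", "SR"):
            cols = [c for c in means.index if c.startswith(metric + "_")]
            vals = " ".join(f"{means[c]:.4g}" for c in cols)
            lines.append(f"{metric:>4}: {vals}")
    else:
        warnings_.append("metrics.csv missing")

    tpath = out / "transitions.npy"
    if tpath.exists():
        trans = np.load(tpath).mean(axis=0)
        lines.append("\n== group-mean transition matrix (self-excluded) ==")
        for row in trans:
            lines.append("  " + " ".join(f"{v:.3f}" for v in row))

    bpath = out / "band_assignment.csv"
    if bpath.exists():
        b = pd.read_csv(bpath)
        lines.append("\n== band of interest per state ==")
        lines.append("  " + " ".join(f"s{r.state}:band{r.band}" for r in b.itertuples()))
    elif (out / "manifest.json").exists():
        warnings_.append("band_assignment.csv missing")

    ppath = out / "pls_summary.json"
    if ppath.exists():
        s = json.loads(ppath.read_text())
        lines.append("\n== PLS ==")
        lines.append("  singular values: " + " ".join(f"{v:.3g}" for v in s["singular_values"]))
        lines.append("  explained fraction: " + " ".join(f"{v:.3f}" for v in s["explained_fraction"]))
        lines.append("  perm p (FDR): " + " ".join(f"{v:.4f}" for v in s["perm_p_fdr"]))
        bsr = pd.read_csv(out / "bsr_cognitive.csv", index_col=0)
        salient = bsr[(bsr.abs() >= 3).any(axis=1)]
        lines.append("  salient cognitive features (|BSR| >= 3): " + ", ".join(salient.index))
    else:
        warnings_.append("pls_summary.json missing")

    for w in warnings_:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"
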