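"""End-to-end orchestration: simulate -> spectral -> connect -> topology -> stats.

Each stage reads the previous stage's on-disk artifacts and persists its own,
so stages can be rerun independently.  Conventions:

* tabular outputs are comma-separated text with a header row;
* per-subject bulk arrays (phases, PLI stacks) are ``.npz`` containers;
* the run report is machine-readable JSON (package and library versions,
  seed, config hash, per-stage outputs) plus a human-readable summary.

A rerun with identical configuration and seed reproduces identical numerical
outputs: every random draw traces to the configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import pli_matrix
from .spectral import DEFAULT_BANDS, Band, subject_phase_epochs
from .stats import correlate_with_clinical, fdr_correct, permutation_test
from .synthdata import CohortSpec, CouplingGraph, generate_cohort, load_subject, write_cohort
from .topology import subject_average, tree_metrics

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "run_pipeline",
    "cohort_global_metrics",
]


def cohort_global_metrics(
    spec: CohortSpec,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    target_fs: float | str | None = "auto",
) -> pd.DataFrame:
    """Generate a cohort and compute epoch-averaged global MST metrics in memory.

    Convenience path for simulation studies (calibration, power): no
    intermediate files.  Returns one row per subject x band with columns
    subject_id, group, band, leaf_fraction, degree_divergence,
    clinical_score.  ``target_fs="auto"`` halves a 1024 Hz acquisition to
    512 Hz and leaves other rates untouched.
    """
    recordings, manifest = generate_cohort(spec)
    if target_fs == "auto":
        target_fs = 512.0 if spec.fs_acquisition % 512.0 == 0 else None
    rows = []
    scores = manifest.set_index("subject_id")["clinical_score"]
    for rec in recordings:
        phase_epochs = subject_phase_epochs(
            rec.data,
            rec.fs,
            subject_id=rec.subject_id,
            pad_seconds=rec.pad_seconds,
            target_fs=target_fs,
            epoch_length=spec.epoch_length,
            n_epochs=spec.n_epochs,
            bands=bands,
        )
        per_band: dict[str, list] = {}
        for pe in phase_epochs:
            per_band.setdefault(pe.band.name, []).append(
                tree_metrics(pli_matrix(pe))
            )
        for band_name, per_epoch in per_band.items():
            sm = subject_average(per_epoch, rec.subject_id, band_name)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "band": band_name,
                    "leaf_fraction": sm.leaf_fraction,
                    "degree_divergence": sm.degree_divergence,
                    "clinical_score": scores.loc[rec.subject_id],
                }
            )
    return pd.DataFrame(rows)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (caught before computation)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending item."""


def _coupling_from_dict(d: dict) -> CouplingGraph:
    edges = d.get("edges")
    return CouplingGraph(
        topology=d["topology"],
        strength=float(d.get("strength", 0.8)),
        edges=tuple((int(i), int(j)) for i, j in edges) if edges else None,
    )


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    out_dir: Path
    seed: int | None = None
    simulate: bool = True
    cohort: CohortSpec | None = None
    manifest: Path | None = None  # existing data when simulate=False
    subject_format: str = "npy"
    bands: tuple[Band, ...] = DEFAULT_BANDS
    epoch_length: float = 8.0
    n_epochs: int = 10
    target_fs: float | None = 512.0
    trim_samples: int = 0
    n_perm: int = 10_000
    alpha: float = 0.05
    outlier_policy: str = "none"
    outlier_ids: tuple = ()
    outlier_threshold: float = 2.5
    corr_band: str = "beta"
    corr_metric: str = "degree_divergence"

    @classmethod
    def from_dict(cls, raw: dict, out_dir: str | Path, seed: int | None = None) -> "RunConfig":
        raw = dict(raw)
        cohort_raw = raw.pop("cohort", None)
        simulate = bool(raw.pop("simulate", cohort_raw is not None))
        if seed is None:
            seed = raw.pop("seed", None)
        else:
            raw.pop("seed", None)
        cohort = None
        if simulate:
            if seed is None:
                raise ConfigError("a seed is required when simulating")
            cohort_raw = dict(cohort_raw or {})
            for key in ("coupling_graph_patients", "coupling_graph_controls"):
                if key in cohort_raw:
                    cohort_raw[key] = _coupling_from_dict(cohort_raw[key])
            if "carrier_band" in cohort_raw:
                cohort_raw["carrier_band"] = tuple(cohort_raw["carrier_band"])
            try:
                cohort = CohortSpec(seed=int(seed), **cohort_raw)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid cohort spec: {exc}") from exc
        manifest = raw.pop("manifest", None)
        if manifest is not None:
            manifest = Path(manifest)
            if not manifest.exists():
                raise ConfigError(f"manifest not found: {manifest}")
        bands_raw = raw.pop("bands", None)
        bands = (
            tuple(Band(b["name"], float(b["low"]), float(b["high"])) for b in bands_raw)
            if bands_raw
            else DEFAULT_BANDS
        )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "target_fs" in raw and raw["target_fs"] is not None:
            raw["target_fs"] = float(raw["target_fs"])
        return cls(
            out_dir=Path(out_dir),
            seed=None if seed is None else int(seed),
            simulate=simulate,
            cohort=cohort,
            manifest=Path(manifest) if manifest else None,
            bands=bands,
            **raw,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path, seed: int | None = None) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, out_dir, seed)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, (np.integer, np.floating)):
                return float(o)
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------- stages


def stage_simulate(config: RunConfig) -> Path:
    """Generate the synthetic cohort and write subject files + manifest."""
    assert config.cohort is not None
    out = config.out_dir / "simulate"
    recordings, manifest = generate_cohort(config.cohort)
    return write_cohort(recordings, manifest, out, fmt=config.subject_format)


def stage_spectral(config: RunConfig, manifest_path: Path) -> Path:
    """Filter, resample, epoch, band-decompose and phase-transform each subject.

    Writes one ``<subject>_phases.npz`` per subject holding a float32 array
    ``phases`` of shape (n_epochs, n_bands, n_rois, n_samples) plus the band
    names, and ``spectral_manifest.csv``.
    """
    out = config.out_dir / "spectral"
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    rows = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        try:
            rec = load_subject(row, manifest_path.parent)
            epochs = subject_phase_epochs(
                rec.data,
                rec.fs,
                subject_id=sid,
                pad_seconds=rec.pad_seconds,
                target_fs=config.target_fs,
                epoch_length=config.epoch_length,
                n_epochs=config.n_epochs,
                bands=config.bands,
                trim_samples=config.trim_samples,
            )
        except Exception as exc:
            raise StageError(f"spectral stage failed for subject {sid}: {exc}") from exc
        n_bands = len(config.bands)
        stack = np.stack([pe.data for pe in epochs]).reshape(
            config.n_epochs, n_bands, rec.data.shape[0], -1
        )
        fpath = out / f"{sid}_phases.npz"
        np.savez(fpath, phases=stack.astype(np.float32),
                 bands=np.array([b.name for b in config.bands]), fs=epochs[0].fs)
        rows.append({**row.to_dict(), "path": fpath.name})
    pd.DataFrame(rows).to_csv(out / "spectral_manifest.csv", index=False)
    return out


def stage_connect(config: RunConfig, spectral_dir: Path) -> Path:
    """Compute the PLI adjacency stack per subject (epochs x bands x N x N)."""
    out = config.out_dir / "connect"
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(spectral_dir / "spectral_manifest.csv")
    rows = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        try:
            with np.load(spectral_dir / str(row["path"])) as npz:
                phases = npz["phases"].astype(float)
                bands = [str(b) for b in npz["bands"]]
            n_ep, n_bd = phases.shape[:2]
            adj = np.stack([
                [pli_matrix(phases[e, b]) for b in range(n_bd)] for e in range(n_ep)
            ])
        except Exception as exc:
            raise StageError(f"connect stage failed for subject {sid}: {exc}") from exc
        fpath = out / f"{sid}_pli.npz"
        np.savez(fpath, pli=adj, bands=np.array(bands))
        rows.append({**row.to_dict(), "path": fpath.name})
    pd.DataFrame(rows).to_csv(out / "connect_manifest.csv", index=False)
    return out


def stage_topology(config: RunConfig, connect_dir: Path) -> Path:
    """MST metrics per epoch, averaged per subject; tidy CSV outputs."""
    out = config.out_dir / "topology"
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(connect_dir / "connect_manifest.csv")
    global_rows, bc_rows = [], []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        try:
            with np.load(connect_dir / str(row["path"])) as npz:
                adj = npz["pli"]
                bands = [str(b) for b in npz["bands"]]
            for b, band in enumerate(bands):
                per_epoch = [tree_metrics(adj[e, b]) for e in range(adj.shape[0])]
                sm = subject_average(per_epoch, sid, band)
                for metric, value in (
                    ("leaf_fraction", sm.leaf_fraction),
                    ("degree_divergence", sm.degree_divergence),
                ):
                    global_rows.append(
                        {"subject_id": sid, "band": band, "metric": metric, "value": value}
                    )
                bc_rows.extend(
                    {"subject_id": sid, "band": band, "roi": r, "value": v}
                    for r, v in enumerate(sm.betweenness)
                )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"topology stage failed for subject {sid}: {exc}") from exc
    pd.DataFrame(global_rows).to_csv(out / "metrics_global.csv", index=False)
    pd.DataFrame(bc_rows).to_csv(out / "metrics_bc.csv", index=False)
    return out


def stage_stats(config: RunConfig, topology_dir: Path, manifest_path: Path) -> Path:
    """Permutation tests (global + nodal families) and clinical correlation."""
    if config.seed is None:
        raise ConfigError("a seed is required for the stats stage")
    out = config.out_dir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    labels = manifest.set_index("subject_id")["group"]
    glob = pd.read_csv(topology_dir / "metrics_global.csv")
    bc = pd.read_csv(topology_dir / "metrics_bc.csv")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))

    def run_family(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        rows = []
        for key_vals, sub in df.groupby(keys, sort=True):
            sub = sub.set_index("subject_id").loc[labels.index]
            gc = permutation_test(
                sub["value"].to_numpy(),
                labels.to_numpy(),
                n_perm=config.n_perm,
                rng=rng,
            )
            rows.append(dict(zip(keys, np.atleast_1d(key_vals)), observed=gc.observed,
                             p_raw=gc.p_raw, n_permutations=gc.n_permutations))
        res = pd.DataFrame(rows)
        res["p_fdr"] = fdr_correct(res["p_raw"].to_numpy())
        res["significant"] = res["p_fdr"] < config.alpha
        return res

    try:
        global_res = run_family(glob, ["metric", "band"])
        bc_res = run_family(bc.rename(columns={"roi": "area"}), ["area", "band"])
        bc_res.insert(0, "metric", "betweenness")
    except Exception as exc:
        raise StageError(f"stats stage failed in group comparison: {exc}") from exc
    global_res.to_csv(out / "group_comparisons.csv", index=False)
    bc_res.to_csv(out / "bc_comparisons.csv", index=False)

    corr_report: dict = {
        "metric": config.corr_metric,
        "band": config.corr_band,
        "policy": config.outlier_policy,
    }
    patients = manifest[manifest["group"] == "patient"]
    kvals = (
        glob[(glob["metric"] == config.corr_metric) & (glob["band"] == config.corr_band)]
        .set_index("subject_id")["value"]
    )
    scored = patients.dropna(subset=["clinical_score"]) if "clinical_score" in patients else patients.iloc[0:0]
    try:
        cres = correlate_with_clinical(
            kvals.loc[scored["subject_id"]].to_numpy(),
            scored["clinical_score"].to_numpy(),
            subject_ids=list(scored["subject_id"]),
            policy=config.outlier_policy,
            exclude_ids=list(config.outlier_ids) or None,
            threshold=config.outlier_threshold,
        )
        corr_report.update(
            r=cres.r, p=cres.p, n_used=cres.n_used, excluded_ids=cres.excluded_ids
        )
    except ValueError as exc:
        corr_report.update(r=None, p=None, n_used=0, error=str(exc))
    with open(out / "correlation.json", "w") as fh:
        json.dump(corr_report, fh, indent=2)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write report.json + summary.txt."""
    import scipy

    if not config.simulate and config.manifest is None:
        raise ConfigError("no manifest: provide a cohort spec (simulate) or a manifest path")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {
        "phasetree_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    manifest_path = config.manifest
    if config.simulate:
        manifest_path = stage_simulate(config)
        report["stages"]["simulate"] = str(manifest_path)
    assert manifest_path is not None
    spectral_dir = stage_spectral(config, manifest_path)
    report["stages"]["spectral"] = str(spectral_dir)
    connect_dir = stage_connect(config, spectral_dir)
    report["stages"]["connect"] = str(connect_dir)
    topology_dir = stage_topology(config, connect_dir)
    report["stages"]["topology"] = str(topology_dir)
    stats_dir = stage_stats(config, topology_dir, manifest_path)
    report["stages"]["stats"] = str(stats_dir)

    global_res = pd.read_csv(stats_dir / "group_comparisons.csv")
    bc_res = pd.read_csv(stats_dir / "bc_comparisons.csv")
    with open(stats_dir / "correlation.json") as fh:
        corr = json.load(fh)
    report["n_global_tests"] = int(len(global_res))
    report["n_bc_tests"] = int(len(bc_res))
    report["significant_global"] = global_res[global_res["significant"]][
        ["metric", "band", "p_fdr"]
    ].to_dict("records")
    report["n_significant_bc"] = int(bc_res["significant"].sum())
    report["correlation"] = corr
    report["runtime_seconds"] = round(time.time() - t0, 2)

    with open(config.out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    lines = [
        f"phasetree {__version__} run (seed={config.seed}, hash={report['config_hash']})",
        f"global-metric family: {report['n_global_tests']} tests, "
        f"{len(report['significant_global'])} significant after FDR",
        f"betweenness family: {report['n_bc_tests']} tests, "
        f"{report['n_significant_bc']} significant after FDR",
        f"clinical correlation ({corr['metric']}, {corr['band']}): "
        f"r={corr.get('r')}, p={corr.get('p')}, n={corr.get('n_used')}",
        f"runtime: {report['runtime_seconds']} s",
    ]
    (config.out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return report
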