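"""Seeded synthetic cohorts of band-limited phase-coupled multichannel signals.

The generator emulates resting-state source-space recordings at the geometry
of a small MEG-style study: 90 regions of interest sampled at 1024 Hz, long
enough for ten 8-s epochs per subject (plus one second of padding at each end
for filter settling), two groups, and per-patient clinical scores linked
linearly to a ground-truth network property.

Generative mechanism
--------------------
Each subject carries a *coupling graph* (a tree, or an explicit forest) over
the ROIs.  A common band-limited Gaussian carrier is generated per connected
component; each node receives a copy of the carrier phase-delayed by the sum
of fixed per-edge lags along the path from the component root, scaled by the
coupling strength, plus independent broadband (0.5-48 Hz) filtered Gaussian
noise.  Per-edge lags are drawn uniformly from [pi/8, 3*pi/8] — bounded away
from 0 and pi, where a sign-of-phase-difference synchronization index loses
sensitivity.  The result is the simplest process with exactly the consistent
nonzero phase-lag structure that the phase lag index measures, so the true
coupling topology (star, chain, random tree, ...) is recoverable downstream
and the minimum-spanning-tree metrics of the estimated network track those of
the planted graph.

Clinical scores for patients are ``clinical_slope * K_true + noise`` truncated
at zero, where ``K_true`` is the degree divergence of the subject's own
coupling graph; controls carry no score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import broadband_filter, _bandpass_sos
from scipy import signal as sps

__all__ = [
    "CouplingGraph",
    "CohortSpec",
    "SubjectRecording",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "load_subject",
]

_LAG_LOW = np.pi / 8
_LAG_HIGH = 3 * np.pi / 8


@dataclass(frozen=True)
class CouplingGraph:
    """Ground-truth coupling topology descriptor.

    ``topology`` is one of ``star``, ``chain``, ``random-tree`` or
    ``explicit``; ``strength`` is the coupling amplitude in [0, 1];
    ``edges`` is required for ``explicit`` and must form a forest.
    """

    topology: str
    strength: float
    edges: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.topology not in ("star", "chain", "random-tree", "explicit"):
            raise ValueError(f"unknown coupling topology {self.topology!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")
        if self.topology == "explicit" and not self.edges:
            raise ValueError("explicit topology requires an edge list")

    def realize(self, n_rois: int, rng: np.random.Generator) -> list[tuple[int, int]]:
        """Materialize the edge list for one subject.

        Star and chain are deterministic; ``random-tree`` draws a uniform
        labelled tree (via a random Pruefer sequence) per subject.
        """
        if self.topology == "star":
            return [(0, j) for j in range(1, n_rois)]
        if self.topology == "chain":
            return [(i, i + 1) for i in range(n_rois - 1)]
        if self.topology == "random-tree":
            return _prufer_tree(n_rois, rng)
        edges = [(min(i, j), max(i, j)) for i, j in self.edges]  # type: ignore[union-attr]
        _validate_forest(edges, n_rois)
        return edges


def _prufer_tree(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random labelled tree on n nodes from a Pruefer sequence."""
    if n == 2:
        return [(0, 1)]
    seq = rng.integers(0, n, size=n - 2)
    degree = np.ones(n, dtype=int)
    for v in seq:
        degree[v] += 1
    edges: list[tuple[int, int]] = []
    import heapq

    leaves = [v for v in range(n) if degree[v] == 1]
    heapq.heapify(leaves)
    for v in seq:
        leaf = heapq.heappop(leaves)
        edges.append((min(leaf, v), max(leaf, v)))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u, w = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((min(u, w), max(u, w)))
    return edges


def _validate_forest(edges: list[tuple[int, int]], n_rois: int) -> None:
    parent = list(range(n_rois))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        if not (0 <= i < n_rois and 0 <= j < n_rois):
            raise ValueError(f"edge ({i},{j}) outside ROI range 0..{n_rois - 1}")
        if i == j:
            raise ValueError(f"self-loop at node {i}")
        ri, rj = find(i), find(j)
        if ri == rj:
            raise ValueError("explicit coupling edges contain a cycle; a forest is required")
        parent[ri] = rj


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults reproduce the reference recording geometry: 90 ROIs at 1024 Hz,
    ten 8-s epochs per subject, beta-band (13-30 Hz) carrier, ten patients
    and ten matched controls.
    """

    n_patients: int = 10
    n_controls: int = 10
    n_rois: int = 90
    fs_acquisition: float = 1024.0
    epoch_length: float = 8.0
    n_epochs: int = 10
    carrier_band: tuple[float, float] = (13.0, 30.0)
    coupling_graph_patients: CouplingGraph = field(
        default_factory=lambda: CouplingGraph("random-tree", 0.8)
    )
    coupling_graph_controls: CouplingGraph = field(
        default_factory=lambda: CouplingGraph("star", 0.8)
    )
    noise_sd: float = 1.0
    clinical_slope: float = 5.0
    clinical_noise_sd: float = 1.0
    pad_seconds: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 3:
            raise ValueError("n_rois must be at least 3")
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be nonnegative")
        n = self.epoch_length * self.fs_acquisition
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_length * fs_acquisition must be an integer")
        lo, hi = self.carrier_band
        if not (0 < lo < hi < self.fs_acquisition / 2):
            raise ValueError("carrier band must lie inside (0, fs/2)")
        if self.noise_sd < 0 or self.clinical_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")

    @property
    def n_samples(self) -> int:
        """Samples per subject including the settling padding."""
        return int(
            round((self.n_epochs * self.epoch_length + 2 * self.pad_seconds)
                  * self.fs_acquisition)
        )


@dataclass
class SubjectRecording:
    """One subject's ROI x sample matrix with metadata."""

    subject_id: str
    group: str  # "patient" | "control"
    data: np.ndarray
    fs: float
    ground_truth_graph: list[tuple[int, int]] | None = None
    clinical_score: float | None = None
    pad_seconds: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


def degree_divergence_of_edges(edges: list[tuple[int, int]], n_nodes: int) -> float:
    """<k^2>/<k> of a graph given as an edge list over ``n_nodes`` nodes."""
    deg = np.zeros(n_nodes)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    if deg.sum() == 0:
        raise ValueError("empty graph has no degree divergence")
    return float(np.mean(deg**2) / np.mean(deg))


def _component_roots(edges: list[tuple[int, int]], n_rois: int):
    """Group coupled nodes into components; yields (root, {node: cum_lag_slot}).

    The lag slot is filled later; here we return BFS orders per component.
    """
    adj: dict[int, list[int]] = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    seen: set[int] = set()
    comps = []
    for start in sorted(adj):
        if start in seen:
            continue
        order = [start]
        seen.add(start)
        k = 0
        while k < len(order):
            for nb in sorted(adj[order[k]]):
                if nb not in seen:
                    seen.add(nb)
                    order.append(nb)
            k += 1
        comps.append(order)
    return comps, adj


def generate_subject(
    spec: CohortSpec, group: str, rng: np.random.Generator, subject_id: str = "s000"
) -> SubjectRecording:
    """Generate one subject's coupled multichannel recording.

    Signal contract: for each edge (i, j) of the subject's coupling graph,
    node j's coupled component is node i's carrier delayed by a fixed
    per-edge phase lag in [pi/8, 3*pi/8]; every coupled node's carrier copy
    is scaled by the coupling strength, and every ROI receives independent
    broadband filtered Gaussian noise.  Output length is
    ``n_epochs * epoch_length + 2 * pad_seconds`` seconds.
    """
    graph = (
        spec.coupling_graph_patients if group == "patient"
        else spec.coupling_graph_controls
    )
    edges = graph.realize(spec.n_rois, rng)
    lags = {
        (i, j): rng.uniform(_LAG_LOW, _LAG_HIGH) for i, j in edges
    }
    n_samples = spec.n_samples
    fs = spec.fs_acquisition

    data = np.zeros((spec.n_rois, n_samples))
    comps, adj = _component_roots(edges, spec.n_rois)
    sos = _bandpass_sos(*spec.carrier_band, fs)
    for order in comps:
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
        carrier /= carrier.std()
        analytic = sps.hilbert(carrier)
        cum_lag = {order[0]: 0.0}
        for v in order[1:]:
            # parent = the already-visited neighbour (unique in a tree)
            parent = next(nb for nb in adj[v] if nb in cum_lag)
            key = (parent, v) if (parent, v) in lags else (v, parent)
            cum_lag[v] = cum_lag[parent] + lags[key]
        for v, lag in cum_lag.items():
            data[v] += graph.strength * np.real(analytic * np.exp(-1j * lag))

    if spec.noise_sd > 0:
        noise = spec.noise_sd * rng.standard_normal((spec.n_rois, n_samples))
        data += broadband_filter(noise, fs)

    score: float | None = None
    if group == "patient":
        k_true = degree_divergence_of_edges(edges, spec.n_rois)
        score = max(
            0.0,
            spec.clinical_slope * k_true + rng.normal(0.0, spec.clinical_noise_sd)
            if spec.clinical_noise_sd > 0
            else spec.clinical_slope * k_true,
        )

    return SubjectRecording(
        subject_id=subject_id,
        group=group,
        data=data,
        fs=fs,
        ground_truth_graph=edges,
        clinical_score=score,
        pad_seconds=spec.pad_seconds,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecording], pd.DataFrame]:
    """Generate the full cohort plus its manifest.

    Reproducible: equal (spec, seed) yield byte-identical cohorts.  Each
    subject draws from an independent child stream of the cohort seed, so
    adding subjects does not perturb earlier ones.
    """
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_patients + spec.n_controls
    children = root.spawn(n_total)
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    recordings: list[SubjectRecording] = []
    rows = []
    for idx, (group, child) in enumerate(zip(groups, children)):
        sid = f"sub-{idx:03d}"
        rec = generate_subject(spec, group, np.random.default_rng(child), sid)
        recordings.append(rec)
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "clinical_score": rec.clinical_score,
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    return recordings, manifest


def write_cohort(
    recordings: list[SubjectRecording],
    manifest: pd.DataFrame,
    out_dir: str | Path,
    fmt: str = "npy",
) -> Path:
    """Write one file per subject plus ``manifest.csv``; returns manifest path.

    ``fmt`` selects ``npy`` (binary array container) or ``csv`` (delimited
    text, one ROI per row).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("npy", "csv"):
        raise ValueError("fmt must be 'npy' or 'csv'")
    manifest = manifest.copy()
    paths, fss, pads = [], [], []
    for rec in recordings:
        fname = f"{rec.subject_id}.{fmt}"
        fpath = out_dir / fname
        if fmt == "npy":
            np.save(fpath, rec.data)
        else:
            np.savetxt(fpath, rec.data, delimiter=",")
        paths.append(fname)
        fss.append(rec.fs)
        pads.append(rec.pad_seconds)
    manifest["path"] = paths
    manifest["fs"] = fss
    manifest["pad_seconds"] = pads
    mpath = out_dir / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    return mpath


def load_subject(manifest_row: pd.Series, base_dir: str | Path) -> SubjectRecording:
    """Load one subject referenced by a manifest row."""
    fpath = Path(base_dir) / str(manifest_row["path"])
    if fpath.suffix == ".npy":
        data = np.load(fpath)
    else:
        data = np.loadtxt(fpath, delimiter=",")
    score = manifest_row.get("clinical_score")
    score = None if score is None or (isinstance(score, float) and math.isnan(score)) else float(score)
    return SubjectRecording(
        subject_id=str(manifest_row["subject_id"]),
        group=str(manifest_row["group"]),
        data=np.atleast_2d(data),
        fs=float(manifest_row.get("fs", 1024.0)),
        clinical_score=score,
        pad_seconds=float(manifest_row.get("pad_seconds", 0.0)),
    )
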