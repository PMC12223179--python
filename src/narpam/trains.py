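"""Click-train construction and unsupervised click-type clustering.

Stage 2 narrows the detection set to echolocation click trains: maximal
runs of at least 10 consecutive detections whose successive inter-click
intervals all fall in [2 ms, 0.5 s].  Stage 3 groups the remaining
detections into click types: within each 5-min window, detections are
collated into 5-s bins whose composites (mean normalized spectrum + ICI
histogram) form nodes of a similarity graph; edges below the pruning
quantile are removed and a deterministic label-propagation community step
(10 sweeps) assigns click-type labels, with communities holding fewer than
50 member detections discarded.  Finalization then keeps detections that
sit in a surviving cluster, belong to a valid train, and exceed the 120
dB_pp received-level floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .clickdet import ImpulseDetection

log = logging.getLogger(__name__)

__all__ = [
    "ClickTrain",
    "ClusterConfig",
    "ClusterResult",
    "build_click_trains",
    "cluster_detections",
    "finalize_narwhal_detections",
]

ICI_MIN_S = 0.002
ICI_MAX_S = 0.5
MIN_TRAIN_CLICKS = 10


@dataclass
class ClickTrain:
    detections: list[ImpulseDetection]
    icis_s: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.detections)


def build_click_trains(detections: list[ImpulseDetection]) -> list[ClickTrain]:
    """Maximal runs of detections with every successive ICI in [2 ms, 0.5 s].

    Runs shorter than 10 clicks are discarded; the retained trains partition
    their detections (each detection belongs to exactly one train).
    Detections must be time-sorted.
    """
    if not detections:
        return []
    times = np.array([d.time_s for d in detections])
    if np.any(np.diff(times) < 0):
        raise ValueError("detections must be time-sorted")
    icis = np.diff(times)
    ok = (icis >= ICI_MIN_S) & (icis <= ICI_MAX_S)

    trains: list[ClickTrain] = []
    start = 0
    for i in range(len(detections)):
        last = i == len(detections) - 1
        if last or not ok[i]:
            end = i  # inclusive
            if end - start + 1 >= MIN_TRAIN_CLICKS:
                trains.append(
                    ClickTrain(
                        detections=list(detections[start : end + 1]),
                        icis_s=icis[start:end],
                    )
                )
            start = i + 1
    return trains


@dataclass(frozen=True)
class ClusterConfig:
    bin_s: float = 5.0
    window_min: float = 5.0
    min_cluster_size: int = 50
    # "pruning threshold of 90%" is read as a minimum edge similarity of
    # 0.9: a quantile reading keeps a fixed fraction of edges and provably
    # disconnects the larger click type whenever type abundances are
    # unbalanced (fewer surviving edges than a spanning tree needs)
    pruning_threshold: float = 0.90
    pruning_is_quantile: bool = False
    n_iterations: int = 10
    peak_freq_bounds_khz: tuple[float, float] = (15.0, 90.0)
    min_rl_db_pp: float = 118.0
    ici_hist_bin_s: float = 0.010

    def __post_init__(self) -> None:
        if not 0 < self.pruning_threshold < 1:
            raise ValueError("pruning_threshold must be in (0,1)")
        if min(self.bin_s, self.window_min, self.min_cluster_size, self.n_iterations) <= 0:
            raise ValueError("cluster config values must be positive")


@dataclass
class ClusterResult:
    bin_composites: list[dict]          # per-bin mean spectrum + ICI histogram
    labels: np.ndarray                  # cluster id per bin (-1 = unassigned)
    members: list[list[int]]            # detection indices per bin
    detection_labels: dict[int, int]    # detection index -> cluster id


def _prefilter(detections, cfg: ClusterConfig) -> list[int]:
    lo, hi = cfg.peak_freq_bounds_khz
    return [
        i
        for i, d in enumerate(detections)
        if lo <= d.peak_freq_khz <= hi and d.rl_db_pp >= cfg.min_rl_db_pp
    ]


def _bin_composites(detections, idx, cfg: ClusterConfig):
    """Collate detections into 5-s bins inside 5-min windows; build composites."""
    times = np.array([detections[i].time_s for i in idx])
    bins = np.floor(times / cfg.bin_s).astype(int)
    comps, members = [], []
    n_ici = int(round(ICI_MAX_S / cfg.ici_hist_bin_s))
    for b in np.unique(bins):
        sel = [idx[j] for j in np.flatnonzero(bins == b)]
        specs = np.array([detections[i].spectrum for i in sel], dtype=float)
        # normalize each spectrum (dB, peak-aligned at 0) before averaging
        specs = specs - specs.max(axis=1, keepdims=True)
        mean_spec = specs.mean(axis=0)
        t = np.sort([detections[i].time_s for i in sel])
        icis = np.diff(t)
        icis = icis[(icis >= ICI_MIN_S) & (icis <= ICI_MAX_S)]
        # round to the microsecond so intervals sitting exactly on a bin
        # edge land in the same bin for every composite
        hist, _ = np.histogram(np.round(icis, 6), bins=n_ici, range=(0.0, ICI_MAX_S))
        hist = hist.astype(float)
        if hist.sum() > 0:
            hist /= hist.sum()
        comps.append(
            {"bin": int(b), "t_start": b * cfg.bin_s, "spectrum": mean_spec, "ici_hist": hist}
        )
        members.append(sel)
    return comps, members


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _similarity_graph(comps, cfg: ClusterConfig) -> nx.Graph:
    n = len(comps)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    sims = []
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            s = 0.5 * _safe_corr(comps[i]["spectrum"], comps[j]["spectrum"]) + 0.5 * _safe_corr(
                comps[i]["ici_hist"], comps[j]["ici_hist"]
            )
            # round so numerically tied similarities survive the quantile cut
            # together rather than by float noise
            sims.append(round(s, 12))
            pairs.append((i, j))
    if not sims:
        return g
    if cfg.pruning_is_quantile:
        cut = float(np.quantile(sims, cfg.pruning_threshold))
    else:
        cut = cfg.pruning_threshold
    for (i, j), s in zip(pairs, sims):
        if s >= cut:
            g.add_edge(i, j, weight=s)
    return g


def _label_propagation(g: nx.Graph, n_sweeps: int) -> np.ndarray:
    """Chinese-Whispers-style propagation, deterministic.

    Nodes are visited in fixed (time) order; each adopts the label with the
    greatest summed edge weight among its neighbours, ties going to the
    lowest label id.
    """
    labels = {v: v for v in g.nodes}
    order = sorted(g.nodes)
    for _ in range(n_sweeps):
        changed = False
        for v in order:
            nbrs = list(g[v])
            if not nbrs:
                continue
            weight_by_label: dict[int, float] = {}
            for u in nbrs:
                weight_by_label.setdefault(labels[u], 0.0)
                weight_by_label[labels[u]] += g[v][u].get("weight", 1.0)
            best = max(weight_by_label.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            if best != labels[v]:
                labels[v] = best
                changed = True
        if not changed:
            break
    return np.array([labels[v] for v in sorted(g.nodes)])


def cluster_detections(
    detections: list[ImpulseDetection], cfg: ClusterConfig = ClusterConfig()
) -> ClusterResult:
    """Two-stage click-type clustering over 5-s bin composites."""
    idx = _prefilter(detections, cfg)
    if not idx:
        return ClusterResult([], np.array([], dtype=int), [], {})
    comps, members = _bin_composites(detections, idx, cfg)
    if len(comps) < 2:
        log.info("fewer than 2 populated bins: single trivial cluster")
        labels = np.zeros(len(comps), dtype=int)
    else:
        g = _similarity_graph(comps, cfg)
        labels = _label_propagation(g, cfg.n_iterations)

    # drop communities with fewer than min_cluster_size member detections
    sizes: dict[int, int] = {}
    for lab, mem in zip(labels, members):
        sizes[lab] = sizes.get(lab, 0) + len(mem)
    final = np.array(
        [lab if sizes[lab] >= cfg.min_cluster_size else -1 for lab in labels]
    )
    # relabel surviving clusters to consecutive ids ordered by first bin
    remap: dict[int, int] = {}
    for lab in final:
        if lab >= 0 and lab not in remap:
            remap[lab] = len(remap)
    final = np.array([remap.get(lab, -1) for lab in final])

    det_labels: dict[int, int] = {}
    for lab, mem in zip(final, members):
        if lab >= 0:
            for i in mem:
                det_labels[i] = int(lab)
    return ClusterResult(comps, final, members, det_labels)


def finalize_narwhal_detections(
    detections: list[ImpulseDetection],
    cluster_result: ClusterResult,
    trains: list[ClickTrain],
    min_rl_db_pp: float = 120.0,
) -> tuple[list[int], dict[str, int]]:
    """Rule-based finalization of the narwhal detection set.

    Retains detection indices that (a) belong to a surviving cluster,
    (b) belong to a valid click train, and (c) exceed ``min_rl_db_pp``.
    Returns the retained indices and per-criterion exclusion counts.
    Lowering the level floor can only grow the retained set (monotone).
    """
    in_train: set[int] = set()
    by_id = {id(d): i for i, d in enumerate(detections)}
    for tr in trains:
        for d in tr.detections:
            in_train.add(by_id[id(d)])

    counts = {"not_in_cluster": 0, "not_in_train": 0, "below_rl": 0}
    kept: list[int] = []
    for i, d in enumerate(detections):
        ok = True
        if i not in cluster_result.detection_labels:
            counts["not_in_cluster"] += 1
            ok = False
        if i not in in_train:
            counts["not_in_train"] += 1
            ok = False
        if not d.rl_db_pp > min_rl_db_pp:
            counts["below_rl"] += 1
            ok = False
        if ok:
            kept.append(i)
    return kept, counts
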