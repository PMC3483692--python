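"""Stage-structured downstream analysis.

The nine sampled stages of cotton somatic embryogenesis fall into three
developmental processes: dedifferentiation of somatic cells (0h -> 6h ->
24h -> 48h -> NEC), the transition from non-embryogenic to embryogenic
callus (NEC -> EC), and somatic-embryo development (EC -> GE -> TE ->
CE). Differential-expression results over the consecutive-stage
comparisons are summarized as up/down histograms, a three-process Venn
partition, and expression-profile clusters.

Clustering uses Pearson correlation distance, d = 1 - r, on per-gene
standardized log2(TPM+1) profiles. Standardized profiles rescaled to
unit norm make this equivalent to squared Euclidean k-means
(||u - v||^2 = 2 (1 - r)), so plain Lloyd iteration minimizes the
within-cluster Pearson scatter and its objective is non-increasing. The
number of clusters can be chosen by the leave-one-stage-out figure of
merit: cluster on all stages but one, score the root-mean-square
deviation of the held-out stage from its cluster means, and take the
smallest k whose relative improvement at k+1 falls below 10%.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_STAGES = ("0h", "6h", "24h", "48h", "NEC", "EC", "GE", "TE", "CE")

DEDIFFERENTIATION = "dedifferentiation"
TRANSITION = "transition"
DEVELOPMENT = "development"


def _consecutive(stages: Sequence[str]) -> tuple[tuple[str, str], ...]:
    return tuple(zip(stages[:-1], stages[1:]))


@dataclass(frozen=True)
class StageDesign:
    """Ordered stages plus the partition of consecutive comparisons into
    developmental-process windows."""

    stages: tuple[str, ...]
    windows: Mapping[str, tuple[tuple[str, str], ...]]

    def __post_init__(self):
        consecutive = set(_consecutive(self.stages))
        seen: set[tuple[str, str]] = set()
        for process, comparisons in self.windows.items():
            for comp in comparisons:
                if comp not in consecutive:
                    raise ValueError(
                        f"{process} comparison {comp} is not a consecutive pair"
                    )
                if comp in seen:
                    raise ValueError(f"comparison {comp} assigned to two processes")
                seen.add(comp)

    @property
    def comparisons(self) -> tuple[tuple[str, str], ...]:
        return _consecutive(self.stages)

    @property
    def processes(self) -> tuple[str, ...]:
        return tuple(self.windows)


def default_design() -> StageDesign:
    stages = DEFAULT_STAGES
    return StageDesign(
        stages=stages,
        windows={
            DEDIFFERENTIATION: (("0h", "6h"), ("6h", "24h"), ("24h", "48h"),
                                ("48h", "NEC")),
            TRANSITION: (("NEC", "EC"),),
            DEVELOPMENT: (("EC", "GE"), ("GE", "TE"), ("TE", "CE")),
        },
    )


def updown_histogram(
    de_results: Mapping[tuple[str, str], pd.DataFrame],
    design: StageDesign,
) -> pd.DataFrame:
    """Counts of up- and down-regulated DE genes per design comparison."""
    rows = []
    for comp in design.comparisons:
        if comp not in de_results:
            raise KeyError(f"missing DE results for comparison {comp}")
        table = de_results[comp]
        de = table[table["is_de"]]
        rows.append(
            {
                "comparison": f"{comp[0]}->{comp[1]}",
                "n_up": int((de["direction"] == "up").sum()),
                "n_down": int((de["direction"] == "down").sum()),
            }
        )
    return pd.DataFrame(rows).set_index("comparison")


def process_members(
    de_results: Mapping[tuple[str, str], pd.DataFrame],
    design: StageDesign,
) -> dict[str, frozenset]:
    """Genes DE in at least one comparison of each process window."""
    members: dict[str, frozenset] = {}
    for process, comparisons in design.windows.items():
        genes: set = set()
        for comp in comparisons:
            if comp not in de_results:
                raise KeyError(f"missing DE results for comparison {comp}")
            table = de_results[comp]
            genes |= set(table.index[table["is_de"]])
        members[process] = frozenset(genes)
    return members


def process_venn(
    de_results: Mapping[tuple[str, str], pd.DataFrame],
    design: StageDesign,
) -> pd.DataFrame:
    """All 2^n - 1 exclusive region counts of the process Venn diagram,
    plus per-process totals and the fraction of DE genes in every process."""
    members = process_members(de_results, design)
    processes = list(members)
    rows = []
    universe: set = set().union(*members.values())
    for size in range(1, len(processes) + 1):
        for combo in itertools.combinations(processes, size):
            inside = set.intersection(*(set(members[p]) for p in combo))
            outside = set().union(
                *(set(members[p]) for p in processes if p not in combo), set()
            )
            exclusive = inside - outside if size < len(processes) else inside
            rows.append(
                {
                    "region": "&".join(combo),
                    "n_genes": len(exclusive),
                }
            )
    venn = pd.DataFrame(rows).set_index("region")
    venn.attrs["process_totals"] = {p: len(members[p]) for p in processes}
    venn.attrs["n_any_process"] = len(universe)
    all_region = "&".join(processes)
    venn.attrs["all_processes_fraction"] = (
        venn.loc[all_region, "n_genes"] / len(universe) if universe else 0.0
    )
    return venn


# ---------------------------------------------------------------------------
# Pearson-distance k-means
# ---------------------------------------------------------------------------

def standardize_profiles(values: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-row z-score scaled to unit norm.

    On these vectors u, the Pearson correlation of two profiles is the dot
    product u . v and 1 - r = ||u - v||^2 / 2. Zero-variance profiles map
    to the zero vector, implementing the r = 0 (d = 1) convention.
    """
    x = np.asarray(values, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(norms > 0, centered / norms, 0.0)
    return u


def kmeans_objective(u: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Sum of squared distances to cluster means in the unit-profile space."""
    obj = 0.0
    for c in range(k):
        mask = labels == c
        if mask.any():
            centroid = u[mask].mean(axis=0)
            obj += float(((u[mask] - centroid) ** 2).sum())
    return obj


@dataclass
class KMeansFit:
    labels: np.ndarray
    centroids: np.ndarray
    objective: float
    objective_history: list[float] = field(default_factory=list)


def _plusplus_init(u: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids by D^2 sampling."""
    n = u.shape[0]
    centroids = np.empty((k, u.shape[1]))
    centroids[0] = u[rng.integers(n)]
    d2 = ((u - centroids[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[c] = u[rng.integers(n)]
            continue
        idx = rng.choice(n, p=d2 / total)
        centroids[c] = u[idx]
        d2 = np.minimum(d2, ((u - centroids[c]) ** 2).sum(axis=1))
    return centroids


def _lloyd(u: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300) -> KMeansFit:
    n = u.shape[0]
    centroids = _plusplus_init(u, k, rng)
    labels = np.full(n, -1)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((u[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # re-seed empty clusters with the worst-fit point
        for c in range(k):
            if not (new_labels == c).any():
                new_labels[d2[np.arange(n), new_labels].argmax()] = c
        obj = kmeans_objective(u, new_labels, k)
        if history and obj > history[-1] + 1e-9:
            raise AssertionError("k-means objective increased")
        history.append(obj)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            mask = labels == c
            centroids[c] = u[mask].mean(axis=0)
    return KMeansFit(labels, centroids, history[-1], history)


def kmeans_pearson(
    profiles: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> KMeansFit:
    """k-means under Pearson distance: best of ``n_restarts`` seeded Lloyd
    runs on unit-standardized profiles, lowest objective kept."""
    u = standardize_profiles(profiles)
    if k > u.shape[0]:
        raise ValueError("k exceeds the number of profiles")
    rng = np.random.default_rng(seed)
    best: KMeansFit | None = None
    for _ in range(n_restarts):
        fit = _lloyd(u, k, rng)
        if best is None or fit.objective < best.objective - 1e-12:
            best = fit
    return best


# ---------------------------------------------------------------------------
# Figure of merit and cluster assignment
# ---------------------------------------------------------------------------

def figure_of_merit(
    values: pd.DataFrame | np.ndarray,
    ks: Sequence[int],
    seed: int = 0,
    n_restarts: int = 5,
) -> pd.Series:
    """Leave-one-stage-out figure of merit per candidate k.

    For every held-out stage, genes are clustered on the remaining stages
    and the contribution is the RMS deviation of the held-out stage's
    z-scored values from their cluster means; contributions are summed
    over stages. Lower is better; the curve decreases in k on average.
    """
    x = np.asarray(values, dtype=float)
    n_genes, n_stages = x.shape
    if n_stages < 4:
        raise ValueError("figure of merit requires at least 4 stages")
    if max(ks) >= n_genes:
        raise ValueError("k must be smaller than the number of genes")
    z = standardize_profiles(x) * np.sqrt(max(n_stages - 1, 1))  # z-scores
    fom = {}
    for k in ks:
        total = 0.0
        for s in range(n_stages):
            train = np.delete(x, s, axis=1)
            fit = kmeans_pearson(train, k, seed=seed + 1000 * s, n_restarts=n_restarts)
            held = z[:, s]
            dev = 0.0
            for c in range(k):
                mask = fit.labels == c
                if mask.any():
                    dev += float(((held[mask] - held[mask].mean()) ** 2).sum())
            total += np.sqrt(dev / n_genes)
        fom[k] = total
    return pd.Series(fom, name="fom")


def select_k(
    values: pd.DataFrame | np.ndarray,
    k_min: int = 2,
    k_max: int = 8,
    rel_improvement: float = 0.10,
    seed: int = 0,
    n_restarts: int = 5,
) -> tuple[int, pd.Series]:
    """Knee of the FOM curve: smallest k whose relative improvement going
    to k+1 drops below ``rel_improvement``; falls back to k_max."""
    ks = list(range(k_min, k_max + 2))
    fom = figure_of_merit(values, ks, seed=seed, n_restarts=n_restarts)
    for k in range(k_min, k_max + 1):
        improvement = (fom[k] - fom[k + 1]) / fom[k] if fom[k] > 0 else 0.0
        if improvement < rel_improvement:
            return k, fom
    return k_max, fom


@dataclass
class ClusterAssignment:
    """Gene -> (type, sub-cluster) plus per-type centroid profiles."""

    assignments: pd.DataFrame   # columns: type, subcluster
    centroids: pd.DataFrame     # type x stage, unit-standardized space
    k: int
    objective: float
    fom: pd.Series | None = None


def cluster_profiles(
    tpm: pd.DataFrame,
    genes: Sequence | None = None,
    k: int | str = 5,
    seed: int = 0,
    n_restarts: int = 10,
    subclusters: bool = True,
) -> ClusterAssignment:
    """Assign expression types (k-means, Pearson distance, log2(TPM+1)
    standardized profiles) and nested sub-clusters within each type.

    ``k="auto"`` chooses the number of types by the FOM knee rule;
    sub-cluster counts (2..4) are chosen per type by the same rule.
    Types are numbered 1..k in decreasing cluster size.
    """
    table = tpm.loc[list(genes)] if genes is not None else tpm
    x = np.log2(table.to_numpy(dtype=float) + 1.0)
    fom = None
    if k == "auto":
        k, fom = select_k(x, seed=seed, n_restarts=n_restarts)
    k = int(k)
    fit = kmeans_pearson(x, k, seed=seed, n_restarts=n_restarts)
    # relabel by decreasing size for stable, readable type ids
    sizes = pd.Series(fit.labels).value_counts()
    relabel = {old: new + 1 for new, old in enumerate(sizes.index)}
    types = np.array([relabel[c] for c in fit.labels])
    sub = np.ones(len(types), dtype=int)
    if subclusters:
        for t in np.unique(types):
            mask = types == t
            members = x[mask]
            if members.shape[0] < 6:
                continue
            k_max_sub = min(4, members.shape[0] - 2)
            if k_max_sub < 2:
                continue
            k_sub, _ = select_k(
                members, k_min=2, k_max=k_max_sub, seed=seed + int(t),
                n_restarts=max(3, n_restarts // 2),
            )
            sub_fit = kmeans_pearson(members, k_sub, seed=seed + int(t),
                                     n_restarts=n_restarts)
            sub_sizes = pd.Series(sub_fit.labels).value_counts()
            sub_relabel = {old: new + 1 for new, old in enumerate(sub_sizes.index)}
            sub[mask] = [sub_relabel[c] for c in sub_fit.labels]
    assignments = pd.DataFrame(
        {"type": types, "subcluster": sub}, index=table.index
    )
    assignments.index.name = "gene"
    centroid_rows = {}
    u = standardize_profiles(x)
    for t in sorted(set(types)):
        centroid_rows[t] = u[types == t].mean(axis=0)
    centroids = pd.DataFrame.from_dict(
        centroid_rows, orient="index", columns=table.columns
    )
    centroids.index.name = "type"
    return ClusterAssignment(
        assignments=assignments,
        centroids=centroids,
        k=k,
        objective=fit.objective,
        fom=fom,
    )
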