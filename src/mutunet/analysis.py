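"""Cross-network ensemble statistics: the per-community metric table,
Spearman rank-correlation matrix, k-means/MDS clustering of metrics, and
bootstrap-supported hierarchical clustering.

The ten observables per network are four architecture metrics (SPE, CON,
NEST, MOD), three stability metrics (RES, ROB, DIS), invasibility (INVb)
and the invasiveness/impact of a reference alien (INVn, IMP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

from .assembly import AssemblyLog, generate_ensemble
from .invasion import (disruptiveness, ensemble_invasion_record,
                       invasibility, invasiveness_impact_grid, resilience,
                       robustness)
from .model import interaction_strength_matrix
from .netmetrics import architecture_metrics

__all__ = [
    "METRIC_COLUMNS",
    "metrics_record",
    "build_metrics_table",
    "spearman_matrix",
    "cluster_metrics",
    "hierarchical_clusters",
    "impact_grid_summary",
    "StudyConfig",
    "StudyResult",
    "run_full_study",
]

METRIC_COLUMNS = ["SPE", "CON", "NEST", "MOD", "RES", "ROB", "DIS",
                  "INVb", "INVn", "IMP"]


def metrics_record(log: AssemblyLog, propagule_fraction: float = 0.10,
                   mode: int = 1, seed: int = 0) -> dict:
    """All ten network observables for one assembled community."""
    comm = log.final_community
    Q = interaction_strength_matrix(comm)
    arch = architecture_metrics(Q, seed=seed)
    rec = ensemble_invasion_record(comm, propagule_fraction, mode)
    p = log.params
    return {
        "SPE": arch.SPE,
        "CON": arch.CON,
        "NEST": arch.NEST,
        "MOD": arch.MOD,
        "RES": resilience(comm),
        "ROB": robustness(Q),
        "DIS": disruptiveness(comm),
        "INVb": invasibility(comm, propagule_fraction, mode),
        "INVn": rec.INVn,
        "IMP": rec.IMP,
        "native_decline": rec.native_decline,
        "n_animals": comm.n,
        "n_plants": comm.m,
        "n_events": log.n_events,
        "sigma_C": p.sigma_C,
        "sigma_m": p.sigma_m,
        "sigma_A": p.sigma_A,
        "seed": log.seed,
    }


def build_metrics_table(logs: Sequence[AssemblyLog],
                        propagule_fraction: float = 0.10, mode: int = 1,
                        seed: int = 0, size_labels: Optional[Sequence[str]] = None,
                        progress: bool = False) -> pd.DataFrame:
    rows = []
    for i, log in enumerate(logs):
        row = metrics_record(log, propagule_fraction, mode, seed=seed + i)
        if size_labels is not None:
            row["size_class"] = size_labels[i]
        rows.append(row)
        if progress:
            print(f"metrics {i + 1}/{len(logs)}", flush=True)
    return pd.DataFrame(rows)


def spearman_matrix(table: pd.DataFrame,
                    columns: Sequence[str] = METRIC_COLUMNS):
    """Pairwise Spearman rank correlations (tie-corrected) and p-values.

    Constant columns yield NaN for their pairs (undefined, not zero).
    """
    cols = [c for c in columns if c in table.columns]
    data = table[cols].to_numpy(dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 records for correlations")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = data[:, i], data[:, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = spearmanr(xi, xj)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def classical_mds(D: np.ndarray, n_components: int = 2):
    """Classical (Torgerson) multidimensional scaling of a distance matrix."""
    k = D.shape[0]
    J = np.eye(k) - np.ones((k, k)) / k
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.maximum(vals[:n_components], 0.0)
    return vecs[:, :n_components] * np.sqrt(pos)[None, :]


def cluster_metrics(corr: pd.DataFrame, k_range: Sequence[int] = range(1, 7),
                    seed: int = 0, n_restarts: int = 50,
                    var_threshold: float = 0.95):
    """k-means clustering of the metrics in MDS space.

    Metrics are embedded by classical MDS of the distance d = 1 - r; the
    chosen k is the smallest whose between-cluster variance share exceeds
    the threshold (95%).  Returns (best_k, labels, variance_explained).
    """
    r = corr.to_numpy(dtype=float)
    D = 1.0 - r
    emb = classical_mds(D)
    tot = ((emb - emb.mean(axis=0)) ** 2).sum()
    variance = {}
    labels_by_k = {}
    for k in k_range:
        if k >= len(corr):
            variance[k] = 1.0
            labels_by_k[k] = np.arange(len(corr))
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(emb)
        variance[k] = 1.0 - km.inertia_ / tot if tot > 0 else 1.0
        labels_by_k[k] = lab
    best_k = None
    for k in sorted(variance):
        if variance[k] > var_threshold:
            best_k = k
            break
    if best_k is None:
        best_k = max(variance, key=variance.get)
    labels = pd.Series(labels_by_k[best_k], index=corr.index, name="cluster")
    return best_k, labels, variance, emb


def _tree_clusters(Z: np.ndarray, n_leaves: int) -> list[frozenset]:
    members = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n_leaves + step] = merged
        out.append(merged)
    return out


def hierarchical_clusters(table: pd.DataFrame, n_boot: int = 1000,
                          alpha: float = 0.95, seed: int = 0,
                          columns: Sequence[str] = METRIC_COLUMNS):
    """Average-linkage clustering of metrics on d = 1 - r with bootstrap
    cluster support.

    Rows of the metric table are resampled with replacement ``n_boot``
    times; the support of a cluster of the base dendrogram is the fraction
    of bootstrap dendrograms containing the identical metric set.  Clusters
    with support > alpha are reported.
    """
    cols = [c for c in columns if c in table.columns]
    r, _ = spearman_matrix(table, cols)
    D = 1.0 - np.nan_to_num(r.to_numpy(), nan=1.0)
    np.fill_diagonal(D, 0.0)
    D = np.maximum(0.0, (D + D.T) / 2)
    Z = linkage(squareform(D, checks=False), method="average")
    base = _tree_clusters(Z, len(cols))
    counts = {cl: 0 for cl in base}
    rng = np.random.default_rng(seed)
    n = len(table)
    valid_boot = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = table.iloc[idx]
        try:
            rb, _ = spearman_matrix(sub, cols)
        except ValueError:
            continue
        Db = 1.0 - np.nan_to_num(rb.to_numpy(), nan=1.0)
        np.fill_diagonal(Db, 0.0)
        Db = np.maximum(0.0, (Db + Db.T) / 2)
        Zb = linkage(squareform(Db, checks=False), method="average")
        boot_cls = set(_tree_clusters(Zb, len(cols)))
        valid_boot += 1
        for cl in base:
            if cl in boot_cls:
                counts[cl] += 1
    supports = {frozenset(cols[i] for i in cl): c / max(valid_boot, 1)
                for cl, c in counts.items()}
    supported = [set(cl) for cl, s in supports.items()
                 if s > alpha and 1 < len(cl) < len(cols)]
    return Z, supports, supported


def impact_grid_summary(logs: Sequence[AssemblyLog],
                        propagule_fraction: float = 0.10, mode: int = 1,
                        progress: bool = False) -> dict:
    """Mean invasion impact over the full rtv x glr scenario grid.

    Returns the average percentage change of total native density at the
    measurement time across all (network, scenario) trials, and the
    fraction of trials in which the native community declined.
    """
    changes = []
    declines = 0
    trials = 0
    for i, log in enumerate(logs):
        grid = invasiveness_impact_grid(log.final_community,
                                        propagule_fraction=propagule_fraction,
                                        mode=mode)
        for row in grid:
            for out in row:
                changes.append(out.native_change)
                declines += bool(out.native_decline)
                trials += 1
        if progress:
            print(f"impact grid {i + 1}/{len(logs)}", flush=True)
    return {
        "mean_pct_change": 100.0 * float(np.mean(changes)),
        "mean_pct_reduction": -100.0 * float(np.mean(changes)),
        "decline_fraction": declines / trials,
        "n_trials": trials,
    }


@dataclass
class StudyConfig:
    """Configuration of an end-to-end ensemble study."""

    sizes: dict = field(default_factory=lambda: {"small": 60, "medium": 40})
    seed: int = 0
    propagule_fraction: float = 0.10
    mode: int = 1
    impact_grid_networks: int = 30   # medium networks receiving the 9x9 grid
    n_boot: int = 1000
    alpha: float = 0.95
    progress: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(**d)


@dataclass
class StudyResult:
    table: pd.DataFrame
    spearman_r: pd.DataFrame
    spearman_p: pd.DataFrame
    best_k: int
    cluster_labels: pd.Series
    variance_explained: dict
    embedding: np.ndarray
    linkage: np.ndarray
    cluster_support: dict
    supported_clusters: list
    grid_summary: dict
    manifest: dict

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "metrics_table.csv", index=False)
        self.spearman_r.to_csv(out / "spearman.csv")
        self.spearman_p.to_csv(out / "spearman_pvalues.csv")
        emb = pd.DataFrame(self.embedding, index=self.spearman_r.index,
                           columns=["mds1", "mds2"])
        emb["cluster"] = self.cluster_labels
        emb.to_csv(out / "embedding.csv")
        payload = {
            "best_k": self.best_k,
            "variance_explained": {str(k): v for k, v
                                   in self.variance_explained.items()},
            "supported_clusters": [sorted(c) for c in self.supported_clusters],
            "cluster_support": {"|".join(sorted(k)): v for k, v
                                in self.cluster_support.items()},
            "grid_summary": self.grid_summary,
            "manifest": self.manifest,
        }
        (out / "clusters.json").write_text(json.dumps(payload, indent=2))


def run_full_study(config: StudyConfig) -> StudyResult:
    """End-to-end pipeline: assemble the ensemble across the kernel sweep,
    measure all network metrics, run the reference invasions and the
    scenario grids, and compute the cross-network statistics."""
    logs = generate_ensemble(config.sizes, seed=config.seed,
                             progress=config.progress)
    size_labels = []
    for cls, count in config.sizes.items():
        # generate_ensemble returns logs grouped per size class in order
        size_labels.extend([cls] * count)
    size_labels = size_labels[:len(logs)]
    table = build_metrics_table(logs, config.propagule_fraction, config.mode,
                                seed=config.seed, size_labels=size_labels,
                                progress=config.progress)
    r, p = spearman_matrix(table)
    best_k, labels, variance, emb = cluster_metrics(r, seed=config.seed)
    Z, supports, supported = hierarchical_clusters(
        table, n_boot=config.n_boot, alpha=config.alpha, seed=config.seed)
    mediums = [log for log, lab in zip(logs, size_labels)
               if lab == "medium"][:config.impact_grid_networks]
    if not mediums:
        mediums = logs[:config.impact_grid_networks]
    grid = impact_grid_summary(mediums, config.propagule_fraction,
                               config.mode, progress=config.progress)
    manifest = {
        "sizes": config.sizes,
        "seed": config.seed,
        "propagule_fraction": config.propagule_fraction,
        "mode": config.mode,
        "n_networks": len(logs),
        "impact_grid_networks": len(mediums),
    }
    return StudyResult(table, r, p, best_k, labels, variance, emb, Z,
                       supports, supported, grid, manifest)
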