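"""Time-course marker discovery on averaged spectral counts.

The question this module answers: which surface proteoforms distinguish the
transgene-dependent (F-class) end state from both the starting fibroblasts
(MEF) and the embryonic-stem-cell-like (ESC) state?

The procedure:

1. fold-change flags between named time points (with a pseudocount, since
   spectral counts are small integers);
2. the down-then-up overlap statistic — what fraction of late-upregulated
   proteoforms had been downregulated at the start of reprogramming;
3. functional-category composition per time point and its dispersion;
4. PCA of log2(x+1) averaged counts (samples as observations, proteoform
   groups as variables);
5. K-means clustering of per-group z-scored trajectories, then selection of
   clusters that rise after DOX induction and peak at the F-class state;
6. ranking of the selected groups by their loading contribution on the
   principal components that best separate F-class from ESC and F-class
   from MEF — the marker score is the smaller of the two contributions, so
   a top marker must separate from both reference states.

ΔΔCt relative quantification and hierarchical clustering are included for
the qPCR validation panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .quantification import CountMatrix, StateError

DEFAULT_THETA = 2.0
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_K = 10


def _require_averaged(matrix: CountMatrix) -> None:
    if matrix.state != "averaged":
        raise StateError(f"expected an averaged matrix, got {matrix.state!r}")


# ---------------------------------------------------------------------------
# fold changes and the down-then-up overlap
# ---------------------------------------------------------------------------

def fold_changes(
    matrix: CountMatrix,
    pairs,
    theta: float = DEFAULT_THETA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Ratios and up/down flags for ordered (early, late) column pairs.

    ratio = (late + c) / (early + c); flag ``up`` if ratio >= theta,
    ``down`` if ratio <= 1/theta, else ``none``. Long format: one row per
    group per pair.
    """
    _require_averaged(matrix)
    if theta <= 1:
        raise ValueError("fold-change threshold theta must exceed 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    rows = []
    for early, late in pairs:
        for col in (early, late):
            if col not in matrix.values.columns:
                raise KeyError(f"column {col!r} not in matrix")
        ratio = (matrix.values[late] + pseudocount) / (
            matrix.values[early] + pseudocount
        )
        flag = np.where(ratio >= theta, "up", np.where(ratio <= 1 / theta, "down", "none"))
        rows.append(
            pd.DataFrame(
                {
                    "primary_id": matrix.values.index,
                    "early": early,
                    "late": late,
                    "ratio": ratio.values,
                    "flag": flag,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def down_up_overlap(
    matrix: CountMatrix,
    early_pair: tuple[str, str],
    late_pair: tuple[str, str],
    theta: float = DEFAULT_THETA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Percentage of late-upregulated groups that were early-downregulated.

    100 * |{up in late_pair} ∩ {down in early_pair}| / |{up in late_pair}|.
    Raises when no group is upregulated in the late pair (the denominator
    would be empty).
    """
    fc = fold_changes(matrix, [early_pair, late_pair], theta, pseudocount)
    early = fc[(fc.early == early_pair[0]) & (fc.late == early_pair[1])]
    late = fc[(fc.early == late_pair[0]) & (fc.late == late_pair[1])]
    late_up = set(late.loc[late.flag == "up", "primary_id"])
    if not late_up:
        raise ValueError("no upregulated group in the late pair; overlap undefined")
    early_down = set(early.loc[early.flag == "down", "primary_id"])
    return 100.0 * len(late_up & early_down) / len(late_up)


# ---------------------------------------------------------------------------
# functional-category composition
# ---------------------------------------------------------------------------

def category_dispersion(
    matrix: CountMatrix,
    annotations: dict[str, str],
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Category percentages per time point and their spread over time.

    At each time point the proteoform groups detected there (count > 0) are
    tabulated by functional category as percentages summing to 100
    (unannotated groups fall in "other"). Returns the percentage table
    (category x time point), the per-category sample s.d. across time
    points, and the unweighted mean of those s.d. values.
    """
    _require_averaged(matrix)
    cats = pd.Series(
        [annotations.get(g, "other") for g in matrix.values.index],
        index=matrix.values.index,
    )
    percent = {}
    for col in matrix.values.columns:
        detected = matrix.values.index[matrix.values[col] > 0]
        if len(detected) == 0:
            warnings.warn(f"no group detected at {col!r}; column skipped")
            continue
        counts = cats.loc[detected].value_counts()
        percent[col] = 100.0 * counts / counts.sum()
    table = pd.DataFrame(percent).fillna(0.0)
    if table.shape[1] < 2:
        warnings.warn("fewer than two time points; dispersion reported as 0")
        sd = pd.Series(0.0, index=table.index)
    else:
        sd = table.std(axis=1, ddof=1)
    return table, sd, float(sd.mean()) if len(sd) else 0.0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Scores (sample x PC), loadings (group x PC) and variance ratios."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray


def run_pca(matrix: CountMatrix, scale: bool = False) -> PCAResult:
    """PCA of the averaged matrix after a log2(x+1) transform.

    Samples (time points) are observations, proteoform groups variables;
    each variable is centred, and optionally scaled to unit variance
    (off by default — spectral counts already share a scale). All
    min(n_samples, n_groups) components are kept, so the explained-variance
    ratios sum to 1 and scores preserve pairwise sample distances.
    """
    _require_averaged(matrix)
    if matrix.values.shape[0] < 2 or matrix.values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 groups and 2 samples")
    X = np.log2(matrix.values.to_numpy(dtype=float).T + 1.0)  # samples x groups
    if np.allclose(X, X[0]):
        raise ValueError("matrix is constant across samples; PCA undefined")
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    comp_labels = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.columns, columns=comp_labels),
        loadings=pd.DataFrame(
            pca.components_.T, index=matrix.values.index, columns=comp_labels
        ),
        variance_explained=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# trajectory clustering and F-class cluster selection
# ---------------------------------------------------------------------------

def standardize_trajectories(matrix: CountMatrix) -> pd.DataFrame:
    """Per-group z-score across time points; flat groups map to all-zero."""
    _require_averaged(matrix)
    vals = matrix.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    z = vals.sub(mean, axis=0).div(sd.replace(0.0, 1.0), axis=0)
    return z


def cluster_trajectories(
    matrix: CountMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    restarts: int = 10,
) -> pd.Series:
    """K-means on z-scored trajectories; best of ``restarts`` inits.

    Deterministic for a fixed seed. Groups with identical trajectories land
    in the same cluster (their standardized rows coincide).
    """
    _require_averaged(matrix)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > matrix.values.shape[0]:
        raise ValueError(
            f"k={k} exceeds the number of groups ({matrix.values.shape[0]})"
        )
    z = standardize_trajectories(matrix)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    return pd.Series(labels, index=z.index, name="cluster")


def _column_roles(matrix: CountMatrix):
    """Identify day-0, first post-induction and F-class end-state columns."""
    points = matrix.column_points
    if not points:
        raise ValueError("averaged matrix lacks column point metadata")
    day0 = min(points.values(), key=lambda p: p[0])[0]
    day0_cols = [c for c, (d, _) in points.items() if d == day0]
    doxh = {c: d for c, (d, cond) in points.items() if cond == "DOXH"}
    if not doxh:
        raise ValueError("no DOXH (F-class trajectory) sample in design")
    later = [d for d in doxh.values() if d > day0]
    if not later:
        raise ValueError("no post-induction DOXH sample in design")
    post_day = min(later)
    post_cols = [c for c, d in doxh.items() if d == post_day]
    end_day = max(doxh.values())
    # the F-class state is the late sustained-DOX phase (final ~40% of the
    # course, e.g. day 18 onward of 30), not the single final sampling day
    fclass_cols = [c for c, d in doxh.items() if d >= 0.6 * end_day]
    return day0_cols, post_cols, fclass_cols


def select_fclass_clusters(
    clusters: pd.Series,
    matrix: CountMatrix,
    design=None,
) -> set[int]:
    """Clusters whose mean trajectory rises after DOX induction and peaks
    at the F-class end state.

    Selection is on the mean z-scored trajectory of each cluster: (a) the
    mean at the first post-induction DOXH point exceeds the day-0 mean, and
    (b) the maximum over all points is attained at an F-class end-state
    column.
    """
    day0_cols, post_cols, fclass_cols = _column_roles(matrix)
    z = standardize_trajectories(matrix)
    selected: set[int] = set()
    for cid in sorted(clusters.unique()):
        mean_traj = z.loc[clusters.index[clusters == cid]].mean(axis=0)
        rises = mean_traj[post_cols].mean() > mean_traj[day0_cols].mean()
        peak_col = mean_traj.idxmax()
        if rises and peak_col in fclass_cols:
            selected.add(int(cid))
    return selected


# ---------------------------------------------------------------------------
# marker ranking from PC loadings
# ---------------------------------------------------------------------------

@dataclass
class MarkerAnalysisResult:
    """Bundle of the full marker-discovery output."""

    pca: PCAResult
    clusters: pd.Series
    selected_clusters: set[int]
    ranking: pd.DataFrame
    separating_components: dict[str, str] = field(default_factory=dict)


def _separating_component(scores: pd.DataFrame, a_samples, b_samples) -> str:
    """Component carrying the largest centroid gap between the two states.

    The gap is measured in score units, so a component's claim to
    "separate" the states is weighted by the variance it actually explains;
    normalizing each component to unit spread would let near-noise
    components with tiny eigenvalues win on chance alignment.
    """
    best, best_gap = scores.columns[0], -1.0
    for comp in scores.columns:
        col = scores[comp]
        gap = abs(col[a_samples].mean() - col[b_samples].mean())
        if gap > best_gap:
            best, best_gap = comp, gap
    return best


def rank_markers(
    pca: PCAResult,
    selected_groups,
    state_samples: dict[str, list[str]],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Rank candidate markers by loading contribution on the separating PCs.

    ``state_samples`` names the score rows of the F-class, ESC and MEF
    states (keys ``fclass``, ``esc``, ``mef``). For each contrast
    (F-class vs ESC, F-class vs MEF) the separating component is the one
    with the largest standardized centroid difference between the two
    states. A group's contribution on a component is |loading| divided by
    the largest |loading| on that component; the marker score is the
    smaller of its two contributions. Returns the ranking table (descending
    score, ties broken by primary_id) and the chosen components.
    """
    for key in ("fclass", "esc", "mef"):
        if not state_samples.get(key):
            raise ValueError(f"state {key!r} has no samples")
        missing = [s for s in state_samples[key] if s not in pca.scores.index]
        if missing:
            raise KeyError(f"state {key!r} samples not in scores: {missing}")
    comps = {
        "fclass_vs_esc": _separating_component(
            pca.scores, state_samples["fclass"], state_samples["esc"]
        ),
        "fclass_vs_mef": _separating_component(
            pca.scores, state_samples["fclass"], state_samples["mef"]
        ),
    }
    selected = [g for g in pca.loadings.index if g in set(selected_groups)]
    table = pd.DataFrame(index=pd.Index(selected, name="primary_id"))
    for contrast, comp in comps.items():
        col = pca.loadings[comp].abs()
        denom = col.max()
        contrib = col / denom if denom > 0 else col * 0.0
        table[f"contribution_{contrast}"] = contrib.loc[selected]
    table["score"] = table.min(axis=1)
    table = table.sort_values(
        by=["score", "primary_id"], ascending=[False, True],
        kind="mergesort",
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table, comps


def discover_markers(
    matrix: CountMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    restarts: int = 10,
    state_samples: dict[str, list[str]] | None = None,
    scale: bool = False,
) -> MarkerAnalysisResult:
    """End-to-end marker discovery: PCA, clustering, selection, ranking.

    When ``state_samples`` is omitted, the states are inferred from the
    averaged-column metadata: F-class = DOXH end point, MEF = day-0 point,
    ESC = the ESC reference column if present, otherwise the latest
    DOX-withdrawn (DOXL-/DOXH-) point.
    """
    if state_samples is None:
        state_samples = infer_state_samples(matrix)
    pca = run_pca(matrix, scale=scale)
    clusters = cluster_trajectories(matrix, k=k, seed=seed, restarts=restarts)
    selected_ids = select_fclass_clusters(clusters, matrix)
    selected_groups = clusters.index[clusters.isin(selected_ids)]
    ranking, comps = rank_markers(pca, selected_groups, state_samples)
    return MarkerAnalysisResult(
        pca=pca,
        clusters=clusters,
        selected_clusters=selected_ids,
        ranking=ranking,
        separating_components=comps,
    )


def infer_state_samples(matrix: CountMatrix) -> dict[str, list[str]]:
    """Derive F-class / ESC / MEF column labels from averaged-point metadata."""
    points = matrix.column_points
    if not points:
        raise ValueError("averaged matrix lacks column point metadata")
    day0_cols, _, fclass_cols = _column_roles(matrix)
    esc_cols = [c for c, (_, cond) in points.items() if cond == "ESC"]
    if not esc_cols:
        off = {c: d for c, (d, cond) in points.items() if cond in ("DOXL-", "DOXH-")}
        if off:
            last = max(off.values())
            esc_cols = [c for c, d in off.items() if d == last]
    if not esc_cols:
        raise ValueError("no ESC-like reference point in design")
    return {"fclass": fclass_cols, "esc": esc_cols, "mef": day0_cols}


def pca_divergence(
    pca: PCAResult, matrix: CountMatrix, n_components: int = 2
) -> dict[str, float]:
    """Distances from arm end points to the ESC reference in score space.

    Uses the first ``n_components`` score coordinates. The sustained
    DOX-high time course is expected to diverge (end far from ESC) while
    the DOX-withdrawn arms converge (end near ESC).
    """
    points = matrix.column_points
    if not points:
        raise ValueError("averaged matrix lacks column point metadata")
    esc_cols = [c for c, (_, cond) in points.items() if cond == "ESC"]
    if not esc_cols:
        raise ValueError("no ESC reference point")
    comps = pca.scores.columns[: n_components]
    esc = pca.scores.loc[esc_cols, comps].mean(axis=0)
    out: dict[str, float] = {}
    for cond in ("DOXH", "DOXL-", "DOXH-"):
        arm = {c: d for c, (d, cc) in points.items() if cc == cond}
        if not arm:
            continue
        end_day = max(arm.values())
        end_cols = [c for c, d in arm.items() if d == end_day]
        end = pca.scores.loc[end_cols, comps].mean(axis=0)
        out[cond] = float(np.linalg.norm(end - esc))
    return out


# ---------------------------------------------------------------------------
# qPCR validation: ΔΔCt and hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """qPCR cycle thresholds (long format) plus the calibrator sample.

    ``values`` columns: gene, sample_id, ct_target, ct_reference.
    """

    values: pd.DataFrame
    calibrator: str

    def __post_init__(self) -> None:
        required = {"gene", "sample_id", "ct_target", "ct_reference"}
        missing = required - set(self.values.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if (self.values[["ct_target", "ct_reference"]] <= 0).any().any():
            raise ValueError("Ct values must be positive")


def relative_expression_ddct(ct: CtTable) -> pd.DataFrame:
    """Fold change 2^(-ΔΔCt) per gene per sample against the calibrator.

    ΔΔCt = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_calibrator,
    the reference gene being the internal control (e.g. Gapdh).
    """
    df = ct.values
    if df[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct value")
    delta = df.ct_target - df.ct_reference
    wide = pd.DataFrame(
        {"dct": delta.values, "gene": df.gene.values, "sample": df.sample_id.values}
    ).pivot_table(index="gene", columns="sample", values="dct")
    if ct.calibrator not in wide.columns:
        raise ValueError(f"calibrator sample {ct.calibrator!r} absent from table")
    calib = wide[ct.calibrator]
    if calib.isna().any():
        missing = list(wide.index[calib.isna()])
        raise ValueError(f"calibrator Ct missing for genes {missing}")
    ddct = wide.sub(calib, axis=0)
    return 2.0 ** (-ddct)


def hierarchical_cluster(
    expression: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[list, np.ndarray]:
    """Agglomerative clustering of expression rows.

    Returns the ordered leaf labels and the scipy linkage matrix. Merge
    heights are non-decreasing for the default euclidean/average-linkage
    combination.
    """
    if expression.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    if expression.isna().any().any():
        raise ValueError("NaN entries in expression table")
    dist = pdist(expression.to_numpy(dtype=float), metric=metric)
    Z = linkage(dist, method=method)
    order = [expression.index[i] for i in leaves_list(Z)]
    return order, Z
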