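"""ASV-table QC, taxonomy aggregation, alpha/beta diversity, ordination and
PERMANOVA for two-group rumen 16S comparisons.

Conventions: counts are a samples x features pandas DataFrame of
nonnegative integers; alpha indices follow the QIIME-lineage definitions
(bias-corrected Chao1, Gini-Simpson 1 - sum(p^2), Shannon in nats, Pielou
H/ln(S)); beta diversity defaults to Bray-Curtis, with unweighted UniFrac
available when a rooted tree is supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from sklearn.manifold import MDS

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_PREFIX = dict(zip("kpcofg", RANKS))
UNCLASSIFIED = "unclassified"


@dataclass
class ASVTable:
    """Samples x features count matrix with group labels and lineages.

    counts: DataFrame (rows = samples, columns = ASVs/taxa), nonnegative.
    groups: Series sample -> group label (e.g. LME/HME), optional.
    lineages: Series feature -> Greengenes-style lineage string, optional.
    """

    counts: pd.DataFrame
    groups: pd.Series | None = None
    lineages: pd.Series | None = None

    def __post_init__(self):
        c = self.counts
        if (np.asarray(c) < 0).any():
            raise ValueError("counts must be nonnegative")
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("sample and feature ids must be unique")
        if self.groups is not None:
            missing = c.index.difference(self.groups.index)
            if len(missing):
                raise ValueError(f"groups missing for samples: {list(missing)[:5]}")
            self.groups = self.groups.loc[c.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, label: str) -> list[str]:
        if self.groups is None:
            raise ValueError("table has no group map")
        return list(self.groups.index[self.groups == label])


def parse_lineage(s: str) -> dict[str, str]:
    """Parse a `k__Bacteria; p__Firmicutes; ...` lineage string.

    Returns rank -> label with empty/missing segments mapped to
    'unclassified'. Unknown prefixes and segments beyond genus are ignored;
    bare labels without prefixes are assigned by position.
    """
    out = {r: UNCLASSIFIED for r in RANKS}
    if not s or not str(s).strip():
        return out
    parts = [p.strip() for p in str(s).split(";")]
    for i, part in enumerate(parts):
        if len(part) >= 3 and part[1:3] == "__":
            rank = _PREFIX.get(part[0].lower())
            label = part[3:].strip()
        else:
            rank = RANKS[i] if i < len(RANKS) else None
            label = part
        if rank is not None and label:
            out[rank] = label
    return out


def format_lineage(ranks: dict[str, str]) -> str:
    """Inverse of parse_lineage on canonical strings."""
    return "; ".join(
        f"{r[0]}__{'' if ranks.get(r, UNCLASSIFIED) == UNCLASSIFIED else ranks[r]}"
        for r in RANKS
    )


def filter_low_count_asvs(table: ASVTable, min_total: int = 5) -> ASVTable:
    """Drop features whose total count over all samples is < min_total."""
    totals = table.counts.sum(axis=0)
    keep = totals[totals >= min_total].index
    if len(keep) == 0:
        raise ValueError("all features removed by the low-count filter")
    lineages = table.lineages.loc[keep.intersection(table.lineages.index)] \
        if table.lineages is not None else None
    return ASVTable(counts=table.counts[keep].copy(), groups=table.groups,
                    lineages=lineages)


class VennPartition(NamedTuple):
    unique_a: int
    unique_b: int
    shared: int
    shared_percent: int


def shared_percent(unique_a: int, unique_b: int, shared: int) -> int:
    """Shared features as a nearest-integer percent of the union."""
    total = unique_a + unique_b + shared
    if total == 0:
        return 0
    return int(round(shared / total * 100.0))


def venn_partition(table: ASVTable, group_a: str = "LME", group_b: str = "HME") -> VennPartition:
    """Unique/shared feature counts between two groups (presence = summed
    count > 0 within the group)."""
    in_a = table.counts.loc[table.group_samples(group_a)].sum(axis=0) > 0
    in_b = table.counts.loc[table.group_samples(group_b)].sum(axis=0) > 0
    ua = int((in_a & ~in_b).sum())
    ub = int((in_b & ~in_a).sum())
    sh = int((in_a & in_b).sum())
    return VennPartition(ua, ub, sh, shared_percent(ua, ub, sh))


class AlphaDiversity(NamedTuple):
    observed: int
    chao1: float
    shannon: float
    simpson: float
    pielou: float | None


def alpha_diversity(counts, chao1_bias_corrected: bool = True) -> AlphaDiversity:
    """Alpha indices of one sample's feature counts.

    observed = nonzero features; chao1 = S + F1(F1-1)/(2(F2+1))
    (bias-corrected; classic S + F1^2/(2 F2) via flag); shannon = -sum p ln p;
    simpson = 1 - sum p^2 (Gini-Simpson); pielou = shannon/ln(observed),
    None when observed == 1.
    """
    x = np.asarray(counts, dtype=float).ravel()
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample has no diversity")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if chao1_bias_corrected:
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        chao1 = s_obs + (f1 ** 2 / (2.0 * f2) if f2 > 0 else f1 * (f1 - 1) / 2.0)
    p = x[x > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p ** 2).sum())
    pielou = None if s_obs == 1 else shannon / math.log(s_obs)
    return AlphaDiversity(s_obs, float(chao1), shannon, simpson, pielou)


def alpha_diversity_table(table: ASVTable, **kwargs) -> pd.DataFrame:
    """Per-sample alpha indices as a DataFrame."""
    rows = {sid: alpha_diversity(table.counts.loc[sid].to_numpy(), **kwargs)._asdict()
            for sid in table.sample_ids}
    return pd.DataFrame.from_dict(rows, orient="index").astype({"observed": int})


def rarefaction_expected_richness(counts, n: int) -> float:
    """Analytic expected richness of a subsample of size n without
    replacement: E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)].
    """
    x = np.asarray(counts, dtype=float).ravel()
    x = x[x > 0]
    total = int(x.sum())
    if not 1 <= n <= total:
        raise ValueError(f"subsample size must be in [1, {total}]")

    def logcomb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    denom = logcomb(total, n)
    rest = total - x
    terms = np.where(rest >= n, np.exp(logcomb(np.maximum(rest, n), n) - denom), 0.0)
    return float((1.0 - terms).sum())


def rarefaction_curve(table: ASVTable, depths: Iterable[int]) -> pd.DataFrame:
    """Expected richness per sample at each requested depth (NaN past the
    sample's total)."""
    out = {}
    for sid in table.sample_ids:
        c = table.counts.loc[sid].to_numpy()
        tot = int(c.sum())
        out[sid] = {d: (rarefaction_expected_richness(c, d) if d <= tot else np.nan)
                    for d in depths}
    return pd.DataFrame.from_dict(out, orient="index")


def bray_curtis(table: ASVTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity 1 - 2 sum(min)/sum(a+b) between samples.

    A pair of all-zero samples gets distance 0 (with a warning).
    """
    m = table.counts.to_numpy(dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    d = squareform(pdist(m, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair; defining its distance as 0")
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(d, ids=table.sample_ids)


def unweighted_unifrac(table: ASVTable, tree) -> DistanceMatrix:
    """Unweighted (presence/absence) UniFrac over a rooted tree.

    `tree` is a skbio TreeNode or a newick string/path. Features present
    in the table but absent from the tree raise an error listing them.
    """
    if not isinstance(tree, skbio.TreeNode):
        import io as _io

        s = str(tree)
        tree = (skbio.TreeNode.read(_io.StringIO(s)) if "(" in s
                else skbio.TreeNode.read(s))  # newick text vs file path
    tips = {t.name for t in tree.tips()}
    present = table.counts.columns[(table.counts > 0).any(axis=0)]
    missing = sorted(set(present) - tips)
    if missing:
        raise ValueError(f"features missing from tree: {missing}")
    return beta_diversity(
        "unweighted_unifrac",
        table.counts.to_numpy(dtype=int),
        ids=table.sample_ids,
        taxa=table.feature_ids,
        tree=tree,
    )


@dataclass
class OrdinationResult:
    """Sample coordinates plus either eigenvalue variance fractions (PCoA)
    or a Kruskal stress-1 value (NMDS)."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray | None = None
    proportion_explained: np.ndarray | None = None
    stress: float | None = None
    converged: bool = True


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal Coordinates Analysis by eigendecomposition of the
    Gower-centered -D^2/2 matrix.

    Axes are ordered by decreasing eigenvalue; variance fractions are taken
    over the positive eigenvalues; negative eigenvalues (non-Euclidean
    input) are reported in `eigenvalues` uncorrected.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs >= 3 samples")
    a = -0.5 * d ** 2
    centre = np.eye(n) - np.ones((n, n)) / n
    b = centre @ a @ centre
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    coords = np.zeros_like(evecs)
    coords[:, pos] = evecs[:, pos] * np.sqrt(evals[pos])
    k = int(pos.sum()) if n_axes is None else min(n_axes, coords.shape[1])
    frac = np.where(evals > 0, evals, 0.0)
    frac = frac / frac.sum() if frac.sum() > 0 else frac
    return OrdinationResult(
        coordinates=pd.DataFrame(coords[:, :k], index=list(dm.ids),
                                 columns=[f"PCo{i + 1}" for i in range(k)]),
        eigenvalues=evals,
        proportion_explained=frac[:k],
    )


def nmds(dm: DistanceMatrix, ndim: int = 2, seed: int = 0,
         max_iter: int = 300, tol: float = 1e-7) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1, initialised from PCoA.

    Uses iterative monotone (isotonic) regression descent; stress-1 =
    sqrt(sum (dhat - d*)^2 / sum dhat^2).
    """
    d = np.asarray(dm.data, dtype=float)
    if d.shape[0] < ndim + 1:
        raise ValueError("too few samples for the requested dimensionality")
    init = pcoa(dm).coordinates.to_numpy()
    if init.shape[1] < ndim:
        init = np.hstack([init, np.zeros((init.shape[0], ndim - init.shape[1]))])
    model = MDS(n_components=ndim, metric="precomputed", metric_mds=False,
                n_init=1, max_iter=max_iter, eps=tol, random_state=seed,
                normalized_stress=True, init="random")  # overridden below
    coords = model.fit_transform(d, init=init[:, :ndim])
    stress = float(model.stress_)
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids),
                                 columns=[f"NMDS{i + 1}" for i in range(ndim)]),
        stress=stress,
        converged=model.n_iter_ < max_iter,
    )


class PermanovaResult(NamedTuple):
    f: float
    r2: float
    p: float
    n_perm: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray):
    """(SS_between, SS_within, SS_total) from squared distances and labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total - ss_within, ss_within, ss_total


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0,
              exact: bool = False) -> PermanovaResult:
    """PERMANOVA (ADONIS) pseudo-F test of group location on a distance
    matrix.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) under label permutations
    (the +1 convention); with `exact=True` all distinct label arrangements
    are enumerated instead and p = #{F >= F_obs}/#arrangements.
    """
    labels = np.asarray(pd.Series(groups).loc[list(dm.ids)] if isinstance(groups, pd.Series)
                        else groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n, a = len(labels), len(uniq)

    def f_stat(lab):
        ss_b, ss_w, ss_t = _permanova_ss(d2, lab)
        if ss_w <= 0:
            return np.inf if ss_b > 0 else np.nan
        return (ss_b / (a - 1)) / (ss_w / (n - a))

    ss_b, ss_w, ss_t = _permanova_ss(d2, labels)
    if ss_t <= 0:
        return PermanovaResult(np.nan, 0.0, 1.0, 0)
    f_obs = f_stat(labels)
    r2 = ss_b / ss_t

    if exact:
        if n > 16:
            raise ValueError("exact enumeration limited to n <= 16")
        idx_a = combinations(range(n), int(counts[0]))
        fs = []
        for pick in idx_a:
            lab = np.full(n, uniq[1], dtype=object)
            lab[list(pick)] = uniq[0]
            fs.append(f_stat(lab))
        fs = np.asarray(fs, dtype=float)
        p = float(np.mean(fs >= f_obs - 1e-12))
        return PermanovaResult(float(f_obs), float(r2), p, len(fs))

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(labels)) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def aggregate_by_rank(table: ASVTable, rank: str) -> ASVTable:
    """Sum feature counts by taxonomic label at `rank` (kingdom..genus);
    features unassigned at that rank pool into 'unclassified'. Per-sample
    totals are conserved."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    if table.lineages is None:
        raise ValueError("table has no lineage map")
    labels = {
        feat: parse_lineage(table.lineages.get(feat, "")).get(rank, UNCLASSIFIED)
        for feat in table.feature_ids
    }
    agg = table.counts.T.groupby(pd.Series(labels)).sum().T
    agg.columns.name = rank
    return ASVTable(counts=agg, groups=table.groups, lineages=None)


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to proportions."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero samples have no relative abundance")
    return counts.div(totals, axis=0)


def mean_reads_per_sample(total_reads: int, n_samples: int) -> float:
    """Average high-quality sequences per sample, half-up to 2 decimals."""
    from ._util import round_half_up

    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return round_half_up(total_reads / n_samples, 2)
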