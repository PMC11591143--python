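"""LEfSe-style differential-abundance screen and Spearman networks.

The screen is a clean-room reimplementation of the LDA-effect-size idea
for the two-class case: per taxonomic rank, a Kruskal-Wallis test per
feature, Benjamini-Hochberg FDR across the features of that rank, and a
linear-discriminant effect size on per-million-normalized abundances.
A feature passes when q < alpha AND log10(LDA effect) > lda_min; with
per-million scaling an effect of 10^3 means a 0.1% absolute abundance
shift, which is what makes the conventional "log10(LDA) > 3" threshold
meaningful.

Default scoring is deterministic (single LDA fit on all samples) so runs
are exactly reproducible; a seeded bootstrap mode (the original tool's
behavior: 30 rounds of 2/3 subsampling, effects averaged) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_qvalues
from .community import ASVTable, RANKS, aggregate_by_rank, relative_abundance

PER_MILLION = 1_000_000.0


class KWResult(NamedTuple):
    h: float
    p: float


def _tie_corrected_h(ranks: np.ndarray, na: int) -> float:
    """Kruskal-Wallis H from precomputed midranks of the pooled sample."""
    n = ranks.size
    r1 = ranks[:na].sum()
    r2 = ranks[na:].sum()
    h = 12.0 / (n * (n + 1)) * (r1 ** 2 / na + r2 ** 2 / (n - na)) - 3 * (n + 1)
    _, tie_counts = np.unique(ranks, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    return h / correction if correction > 0 else 0.0


def kruskal_wallis_test(a, b, exact: bool | None = None) -> KWResult:
    """Two-sample Kruskal-Wallis with tie correction.

    p comes from the chi-square (df=1) approximation, or from exhaustive
    enumeration of all C(n, na) label splits when `exact=True` (allowed up
    to pooled n = 10; `exact=None` auto-enables it there). All-identical
    input gives H = 0, p = 1.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    n = x.size + y.size
    if n < 4 or x.size == 0 or y.size == 0:
        raise ValueError("need two nonempty groups, pooled n >= 4")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return KWResult(0.0, 1.0)
    ranks = stats.rankdata(pooled)
    h = _tie_corrected_h(ranks, x.size)
    if exact is None:
        exact = n <= 10
    if exact:
        if n > 10 or comb(n, x.size) > 100000:
            raise ValueError("exact enumeration limited to pooled n <= 10")
        hs = []
        idx = np.arange(n)
        for pick in combinations(idx, x.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(pick)] = True
            hs.append(_tie_corrected_h(np.concatenate([ranks[mask], ranks[~mask]]),
                                       x.size))
        hs = np.asarray(hs)
        p = float(np.mean(hs >= h - 1e-12))
    else:
        p = float(stats.chi2.sf(h, df=1))
    return KWResult(float(h), p)


def per_million(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (row) to one million total — LEfSe's working scale."""
    return relative_abundance(counts) * PER_MILLION


@dataclass
class LDAScores:
    effect: pd.Series  # per-feature effect on the abundance scale
    score: pd.Series  # log10(max(effect, 1))
    side: pd.Series  # group with the larger mean


def _fit_lda_direction(x: np.ndarray, y01: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Two-class Fisher discriminant direction with a trace-scaled ridge.

    With p >= n the pooled within-class scatter is singular; the ridge
    (eps * mean diagonal) keeps the solve defined and is logged by the
    caller's docstring contract rather than warned per-call.
    """
    mu0 = x[y01 == 0].mean(axis=0)
    mu1 = x[y01 == 1].mean(axis=0)
    xc = x.copy()
    xc[y01 == 0] -= mu0
    xc[y01 == 1] -= mu1
    n = x.shape[0]
    sw = xc.T @ xc / max(n - 2, 1)
    lam = ridge * max(np.trace(sw) / sw.shape[0], 1e-12)
    w = np.linalg.solve(sw + lam * np.eye(sw.shape[0]), mu1 - mu0)
    nrm = np.linalg.norm(w)
    return w / nrm if nrm > 0 else w


def _effect_sizes(x: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Per-feature LDA effect: mean of |raw class-mean difference| and the
    feature's share of the discriminant-projected mean difference.

    For a single feature this reduces to the raw mean difference, so a
    two-class means 1e5 vs 1e3 per-million scores log10(9.9e4) ~ 5.
    """
    dm = x[y01 == 1].mean(axis=0) - x[y01 == 0].mean(axis=0)
    w = _fit_lda_direction(x, y01)
    proj = float(w @ dm)
    return 0.5 * (np.abs(dm) + np.abs(w * proj))


def lda_effect_size(
    abundances: pd.DataFrame,
    groups: pd.Series | Sequence[str],
    bootstrap: int = 0,
    subsample: float = 2 / 3,
    seed: int = 0,
) -> LDAScores:
    """LDA effect sizes of features between two groups.

    `abundances` must already be on the intended scale (per-million for
    taxa; RPKM for pathways). Deterministic by default; `bootstrap > 0`
    averages effects over seeded 2/3-per-class subsamples.
    """
    g = pd.Series(groups, index=abundances.index) if not isinstance(groups, pd.Series) \
        else groups.loc[abundances.index]
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    y01 = (g == levels[1]).to_numpy().astype(int)
    x = abundances.to_numpy(dtype=float)
    if bootstrap <= 0:
        eff = _effect_sizes(x, y01)
    else:
        rng = np.random.default_rng(seed)
        idx0 = np.flatnonzero(y01 == 0)
        idx1 = np.flatnonzero(y01 == 1)
        k0 = max(2, int(round(subsample * idx0.size)))
        k1 = max(2, int(round(subsample * idx1.size)))
        effs = []
        for _ in range(bootstrap):
            pick = np.concatenate([rng.choice(idx0, k0, replace=False),
                                   rng.choice(idx1, k1, replace=False)])
            effs.append(_effect_sizes(x[pick], y01[pick]))
        eff = np.mean(effs, axis=0)
    feats = abundances.columns
    mean1 = abundances[g == levels[1]].mean(axis=0)
    mean0 = abundances[g == levels[0]].mean(axis=0)
    side = pd.Series(np.where(mean1 >= mean0, levels[1], levels[0]), index=feats)
    effect = pd.Series(eff, index=feats)
    score = np.log10(np.maximum(effect, 1.0))
    return LDAScores(effect=effect, score=pd.Series(score, index=feats), side=side)


def screen_rank_table(
    abundances: pd.DataFrame,
    groups: pd.Series,
    rank: str,
    lda_min: float,
    alpha: float,
    bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """KW + BH + LDA screen of one rank's abundance table (already scaled)."""
    g = groups.loc[abundances.index]
    levels = sorted(g.unique())
    a_idx = (g == levels[0]).to_numpy()
    hs, ps = [], []
    for feat in abundances.columns:
        v = abundances[feat].to_numpy(dtype=float)
        res = kruskal_wallis_test(v[a_idx], v[~a_idx], exact=False)
        hs.append(res.h)
        ps.append(res.p)
    qs = bh_qvalues(ps)
    scores = lda_effect_size(abundances, g, bootstrap=bootstrap, seed=seed)
    out = pd.DataFrame(
        {
            "rank": rank,
            "feature": list(abundances.columns),
            "H": hs,
            "p": ps,
            "q": qs,
            "log10_lda": scores.score.to_numpy(),
            "side": scores.side.to_numpy(),
        }
    )
    out["pass"] = (out["q"] < alpha) & (out["log10_lda"] > lda_min)
    return out


def lefse_screen(
    table: ASVTable,
    ranks: Sequence[str] = ("phylum", "class", "order", "family", "genus"),
    lda_min: float = 3.0,
    alpha: float = 0.05,
    bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Differential taxa across taxonomic ranks.

    Counts are per-million normalized (so results are sequencing-depth
    invariant), aggregated to each rank, and screened; BH-FDR is applied
    within each rank. Returns the effect table for all features with pass
    flags; defaults are the conventional thresholds
    (log10(LDA) > 3, FDR < 0.05).
    """
    if table.groups is None:
        raise ValueError("table needs group labels")
    bad = [r for r in ranks if r not in RANKS]
    if bad:
        raise ValueError(f"unknown ranks: {bad}")
    pieces = []
    for rank in ranks:
        agg = aggregate_by_rank(table, rank)
        norm = per_million(agg.counts)
        pieces.append(
            screen_rank_table(norm, table.groups, rank, lda_min, alpha,
                              bootstrap=bootstrap, seed=seed)
        )
    return pd.concat(pieces, ignore_index=True)


@dataclass
class CorrelationNetwork:
    """Spearman correlations among the dominant taxa of one group."""

    taxa: list[str]
    rho: pd.DataFrame
    q: pd.DataFrame


def spearman_network(
    table: ASVTable, top_k: int = 10, groups: Sequence[str] | None = None
) -> dict[str, CorrelationNetwork]:
    """Per-group Spearman network of the top-k taxa by mean relative
    abundance within that group.

    rho uses average-rank ties; the k(k-1)/2 pairwise p-values are
    BH-adjusted. Pairs involving a constant taxon get rho/q = NaN.
    """
    if table.groups is None:
        raise ValueError("table needs group labels")
    rel = relative_abundance(table.counts)
    out: dict[str, CorrelationNetwork] = {}
    for grp in (sorted(table.groups.unique()) if groups is None else groups):
        sids = table.group_samples(grp)
        sub = rel.loc[sids]
        if sub.shape[1] < top_k:
            raise ValueError(f"fewer than top_k={top_k} taxa present")
        top = sub.mean(axis=0).sort_values(ascending=False).index[:top_k].tolist()
        x = sub[top].to_numpy()
        k = len(top)
        rho = np.full((k, k), np.nan)
        np.fill_diagonal(rho, 1.0)
        praw = np.full((k, k), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            for i in range(k):
                for j in range(i + 1, k):
                    r, p = stats.spearmanr(x[:, i], x[:, j])
                    rho[i, j] = rho[j, i] = r
                    praw[i, j] = praw[j, i] = p
        iu = np.triu_indices(k, 1)
        qflat = bh_qvalues(praw[iu])
        qmat = np.full((k, k), np.nan)
        qmat[iu] = qflat
        qmat.T[iu] = qflat
        out[grp] = CorrelationNetwork(
            taxa=top,
            rho=pd.DataFrame(rho, index=top, columns=top),
            q=pd.DataFrame(qmat, index=top, columns=top),
        )
    return out
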