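"""Methane phenotypes from laser-methane-detector (LMD) traces.

An LMD points a 1653 nm laser at a cow's nostrils and reports methane
column density (ppm x m) ~60 times a minute; a 3-minute session yields
~180 readings. Methane leaves the rumen mostly by eructation (belching),
so the informative part of a trace is its peaks, not its baseline. The
pipeline here is:

1. range-filter each session's readings to [200, 8000] ppm x m,
2. per session, keep only readings strictly above mean + 1 SD and average
   them (the eructation-peak phenotype for that session),
3. per cow, average the session phenotypes (cows need >= 2 valid sessions),
4. population QC at mean +/- 3 SD,
5. select low/high methane-emitting (LME/HME) groups at mean -/+ 0.65 SD
   among cows passing eligibility filters (milk yield 30-40 kg, parity 1-2).

All standard deviations are sample SDs (n-1), matching R's `sd`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import as_1d_float, round_half_up

LME = "LME"
HME = "HME"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Session:
    """One 3-minute LMD measurement of one cow."""

    cow_id: str
    session_id: str
    readings: np.ndarray
    timestamp: str = ""

    def __post_init__(self):
        r = np.asarray(self.readings, dtype=float)
        if r.size == 0:
            raise ValueError("Session.readings must be nonempty")
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise ValueError("Session.readings must be finite and >= 0")
        object.__setattr__(self, "readings", r)


@dataclass(frozen=True)
class SessionPhenotype:
    """Mean of the above-threshold readings of one session."""

    cow_id: str
    session_id: str
    value: float
    n_retained: int
    threshold: float


@dataclass
class CowRecord:
    cow_id: str
    session_values: list[float] = field(default_factory=list)
    phenotype: float | None = None
    parity: int | None = None
    milk_yield: float | None = None
    dim: int | None = None
    group: str = UNASSIGNED


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of a phenotype vector, CV reported in percent."""

    label: str
    n: int
    mean: float
    sd: float
    max: float
    min: float
    cv: float


def filter_range(readings, lo: float = 200.0, hi: float = 8000.0) -> np.ndarray:
    """Drop readings strictly below `lo` or strictly above `hi` (bounds kept).

    Order is preserved; an empty result is legal (the session is later
    discarded).
    """
    r = np.asarray(readings, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("readings must be finite")
    return r[(r >= lo) & (r <= hi)]


def session_phenotype(
    readings, cow_id: str = "", session_id: str = ""
) -> SessionPhenotype | None:
    """Eructation-peak phenotype of one range-filtered session.

    Threshold = mean + sample SD of the session; the phenotype is the mean
    of readings strictly above it. Returns None for invalid sessions:
    fewer than 2 readings (no SD) or no reading above threshold (e.g. a
    zero-variance trace).
    """
    r = np.asarray(readings, dtype=float)
    if r.size < 2:
        return None
    thr = float(np.mean(r) + np.std(r, ddof=1))
    above = r[r > thr]
    if above.size == 0:
        return None
    return SessionPhenotype(
        cow_id=cow_id,
        session_id=session_id,
        value=float(np.mean(above)),
        n_retained=int(above.size),
        threshold=thr,
    )


def cow_phenotype(session_values: Sequence[float], min_sessions: int = 2) -> float | None:
    """Mean of a cow's session phenotypes; None with fewer than `min_sessions`."""
    v = [float(x) for x in session_values]
    if len(v) < min_sessions:
        return None
    return float(np.mean(v))


def population_qc(phenotypes, k: float = 3.0) -> np.ndarray:
    """Single-pass mean +/- k*SD outlier mask over the cow phenotype vector.

    Returns a boolean retain-mask aligned with the input. With SD = 0
    (all-identical input) everything is retained. Not iterated: one pass
    is idempotent on its own output.
    """
    x = as_1d_float(phenotypes, "phenotypes")
    if x.size < 2:
        raise ValueError("population_qc needs at least 2 phenotypes")
    m, s = float(np.mean(x)), float(np.std(x, ddof=1))
    return (x >= m - k * s) & (x <= m + k * s)


def phenotype_sessions(sessions: Iterable[Session], lo: float = 200.0, hi: float = 8000.0):
    """filter_range + session_phenotype over many sessions; invalid ones dropped."""
    out: list[SessionPhenotype] = []
    n_invalid = 0
    for s in sessions:
        ph = session_phenotype(filter_range(s.readings, lo, hi), s.cow_id, s.session_id)
        if ph is None:
            n_invalid += 1
        else:
            out.append(ph)
    return out, n_invalid


def phenotype_cows(
    sessions: Iterable[Session],
    lo: float = 200.0,
    hi: float = 8000.0,
    min_sessions: int = 2,
    qc_k: float = 3.0,
) -> pd.DataFrame:
    """Full trace -> phenotype pipeline.

    Returns a DataFrame indexed by cow_id with columns n_sessions,
    phenotype, qc_pass. Cows with < min_sessions valid sessions get
    phenotype NaN and qc_pass False.
    """
    session_phens, _ = phenotype_sessions(sessions, lo, hi)
    per_cow: dict[str, list[float]] = {}
    for ph in session_phens:
        per_cow.setdefault(ph.cow_id, []).append(ph.value)
    rows = []
    for cid, vals in sorted(per_cow.items()):
        phen = cow_phenotype(vals, min_sessions)
        rows.append((cid, len(vals), np.nan if phen is None else phen))
    df = pd.DataFrame(rows, columns=["cow_id", "n_sessions", "phenotype"]).set_index(
        "cow_id"
    )
    defined = df["phenotype"].notna()
    df["qc_pass"] = False
    if defined.sum() >= 2:
        mask = population_qc(df.loc[defined, "phenotype"].to_numpy(), qc_k)
        df.loc[defined, "qc_pass"] = mask
    return df


def select_groups(
    cows: pd.DataFrame,
    k: float = 0.65,
    milk_lo: float = 30.0,
    milk_hi: float = 40.0,
    parities: set[int] = frozenset({1, 2}),
    reference: str = "population",
) -> pd.DataFrame:
    """Assign LME/HME labels by the mean +/- k*SD extreme-group criterion.

    `cows` needs columns phenotype, milk_yield, parity (rows = QC'd cows
    with defined phenotypes). Eligibility (milk_lo <= milk <= milk_hi,
    parity in parities) is applied first; the cutoff mean/SD come from the
    full QC'd population (`reference="population"`, default) or from the
    eligible subset (`reference="eligible"`). Returns a copy with a
    `group` column in {LME, HME, unassigned}.
    """
    if reference not in ("population", "eligible"):
        raise ValueError("reference must be 'population' or 'eligible'")
    out = cows.copy()
    out["group"] = UNASSIGNED
    eligible = (
        out["milk_yield"].between(milk_lo, milk_hi)
        & out["parity"].isin(list(parities))
        & out["phenotype"].notna()
    )
    ref_vals = out.loc[eligible if reference == "eligible" else out["phenotype"].notna(),
                       "phenotype"].to_numpy(dtype=float)
    if ref_vals.size < 2:
        warnings.warn("too few phenotypes to define cutoffs; no assignments")
        return out
    m, s = float(np.mean(ref_vals)), float(np.std(ref_vals, ddof=1))
    if s == 0:
        warnings.warn("phenotype SD is 0; no group assignments made")
        return out
    lo_cut, hi_cut = m - k * s, m + k * s
    out.loc[eligible & (out["phenotype"] < lo_cut), "group"] = LME
    out.loc[eligible & (out["phenotype"] > hi_cut), "group"] = HME
    return out


def cv_percent(mean: float, sd: float, ndigits: int = 2) -> float:
    """Coefficient of variation sd/mean x 100, half-up rounded for reporting."""
    if mean == 0:
        raise ValueError("CV undefined for mean 0")
    return round_half_up(sd / mean * 100.0, ndigits)


def summarize_group(values, label: str) -> GroupSummary:
    """Descriptive statistics (mean, sample SD, max, min, CV%) of one group."""
    x = as_1d_float(values, "values")
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return GroupSummary(
        label=label,
        n=int(x.size),
        mean=m,
        sd=s,
        max=float(np.max(x)),
        min=float(np.min(x)),
        cv=cv_percent(m, s),
    )


def welch_compare(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t-test (R `t.test` default).

    Returns (t, df, p). The degenerate zero-variance/equal-means case is
    defined as (0, na+nb-2, 1).
    """
    x, y = as_1d_float(a, "a"), as_1d_float(b, "b")
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
        # infinite separation relative to zero noise
        return float(np.inf if np.mean(x) > np.mean(y) else -np.inf), float(
            x.size + y.size - 2
        ), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
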