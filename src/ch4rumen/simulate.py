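"""Synthetic data with known ground truth for every pipeline stage.

The study's raw data (LMD traces, ASV tables, predicted KO tables) are not
deposited, so this module generates structurally faithful stand-ins:

* LMD traces: Gaussian baseline plus boxcar eructation events whose
  amplitude scales with a latent per-cow emission level. ~180 readings per
  3-minute session, 2-4 sessions per cow.
* ASV tables: Dirichlet-multinomial counts per sample with group-modified
  concentrations for a chosen set of spiked taxa (known log2 fold-changes
  in the high-emitting group).
* Predicted-KO tables: gamma-Poisson KO counts with pathway-level group
  effects, plus KO reference lengths and a KO -> level-3 -> level-2
  mapping for RPKM and pathway aggregation.

Everything is reproducible from the spec's seed; ground truth is returned
alongside the data so tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import ASVTable
from .phenotyping import HME, LME, Session

# Dominant rumen phyla/genera used to label synthetic ASVs realistically.
_PHYLA = [
    "Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
    "Tenericutes", "Spirochaetes", "TM7",
]
_CLASSES = {
    "Firmicutes": "Clostridia", "Bacteroidetes": "Bacteroidia",
    "Proteobacteria": "Gammaproteobacteria", "Actinobacteria": "Actinobacteria",
    "Tenericutes": "Mollicutes", "Spirochaetes": "Spirochaetes", "TM7": "TM7_3",
}


@dataclass(frozen=True)
class TraceSimSpec:
    """Study-condition defaults: 60 cows x 3 sessions x 180 readings,
    baseline 450 +/- 60 ppm x m, 4 eructation events/session of amplitude
    600 +/- 100 ppm x m. The between-cow amplitude spread (284 ppm x m)
    mirrors the full-cohort phenotype SD reported for large LMD-measured
    Holstein herds (CV ~ 33%)."""

    n_cows: int = 60
    sessions_per_cow: int = 3
    readings_per_session: int = 180
    baseline_mean: float = 450.0
    baseline_sd: float = 60.0
    eructation_rate: float = 4.0
    eructation_amp_mean: float = 600.0
    eructation_amp_sd: float = 100.0
    event_duration: int = 10
    cow_effect_sd: float = 284.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cows, self.sessions_per_cow, self.readings_per_session,
               self.event_duration) < 1:
            raise ValueError("counts must be positive")
        if self.eructation_rate < 0 or min(self.baseline_sd, self.eructation_amp_sd,
                                           self.cow_effect_sd) < 0:
            raise ValueError("rates and spreads must be nonnegative")
        if self.readings_per_session < self.event_duration:
            raise ValueError("readings_per_session must be >= event_duration")


@dataclass(frozen=True)
class CommunitySimSpec:
    """Defaults mirror the screened cohort scale: 30 samples/group, 200
    taxa, ~20 000 reads/sample, Dirichlet concentration 50."""

    n_per_group: int = 30
    n_taxa: int = 200
    base_proportions: tuple[float, ...] | None = None
    spiked_taxa: tuple[tuple[int, float], ...] = ()  # (taxon index, log2FC in HME)
    depth_mean: int = 20000
    overdispersion: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1 or self.n_taxa < 2 or self.depth_mean < 1:
            raise ValueError("sizes must be positive")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        for idx, fc in self.spiked_taxa:
            if not (0 <= idx < self.n_taxa) or not np.isfinite(fc):
                raise ValueError(f"invalid spike ({idx}, {fc})")

    def proportions(self) -> np.ndarray:
        """Baseline composition; default is a power-law ranked abundance."""
        if self.base_proportions is not None:
            p = np.asarray(self.base_proportions, dtype=float)
            if p.size != self.n_taxa or np.any(p <= 0):
                raise ValueError("base_proportions must be positive, length n_taxa")
        else:
            p = 1.0 / np.arange(1, self.n_taxa + 1, dtype=float)
        return p / p.sum()


@dataclass(frozen=True)
class FunctionSimSpec:
    """Predicted-KO tables: 300 KOs in 30 level-3 pathways (10 KOs each),
    nested 5 level-3 per level-2 category."""

    n_per_group: int = 30
    n_kos: int = 300
    kos_per_pathway: int = 10
    level3_per_level2: int = 5
    depth_mean: int = 200000
    dispersion: float = 0.2  # gamma CV of per-sample KO rates
    effect_pathways: tuple[tuple[int, float], ...] = ()  # (level-3 index, log2FC in HME)
    seed: int = 0


def _session_ids(spec: TraceSimSpec):
    """Day 1 AM, day 1 PM, day 2 AM, ... like the two-day AM/PM protocol."""
    for j in range(spec.sessions_per_cow):
        day, slot = divmod(j, 2)
        yield f"d{day + 1}{'AM' if slot == 0 else 'PM'}", f"2024-06-{day + 1:02d}T{'08' if slot == 0 else '16'}:00:00"


def simulate_lmd_sessions(spec: TraceSimSpec) -> tuple[list[Session], pd.Series]:
    """Simulate LMD traces; returns (sessions, latent per-cow emission level).

    Each cow carries a latent eructation amplitude L ~ N(amp_mean,
    cow_effect_sd) (truncated at 10% of the mean). A session is baseline
    N(baseline_mean, baseline_sd) noise with Poisson(rate) boxcar events;
    each event adds N(L, amp_sd) for event_duration readings. Readings are
    clipped at 0.
    """
    rng = np.random.default_rng(spec.seed)
    floor = 0.1 * spec.eructation_amp_mean
    latent = np.maximum(
        rng.normal(spec.eructation_amp_mean, spec.cow_effect_sd, spec.n_cows), floor
    )
    sessions: list[Session] = []
    cow_ids = [f"cow{i + 1:04d}" for i in range(spec.n_cows)]
    for i, cid in enumerate(cow_ids):
        for sid, ts in _session_ids(spec):
            trace = rng.normal(spec.baseline_mean, spec.baseline_sd,
                               spec.readings_per_session)
            n_events = rng.poisson(spec.eructation_rate)
            for _ in range(n_events):
                start = rng.integers(0, spec.readings_per_session - spec.event_duration + 1)
                amp = max(0.0, rng.normal(latent[i], spec.eructation_amp_sd))
                trace[start:start + spec.event_duration] += amp
            sessions.append(Session(cow_id=cid, session_id=sid,
                                    readings=np.clip(trace, 0, None), timestamp=ts))
    return sessions, pd.Series(latent, index=cow_ids, name="latent_level")


def _lineage(i: int) -> str:
    ph = _PHYLA[i % len(_PHYLA)]
    return (
        f"k__Bacteria; p__{ph}; c__{_CLASSES[ph]}; o__Order{i % 14:02d}; "
        f"f__Family{i % 35:02d}; g__Genus{i:03d}"
    )


def simulate_asv_table(spec: CommunitySimSpec) -> tuple[ASVTable, pd.DataFrame]:
    """Dirichlet-multinomial ASV counts with optional spiked taxa.

    Per sample: proportions ~ Dirichlet(base x overdispersion), with the
    spiked taxa's concentrations multiplied by 2**log2FC in the HME group;
    counts ~ Multinomial(depth, proportions), depth ~ Poisson(depth_mean).
    Returns (table, truth) where truth lists each spiked taxon with its
    fold-change and enriched side.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.proportions() * spec.overdispersion
    alpha = {LME: base.copy(), HME: base.copy()}
    for idx, fc in spec.spiked_taxa:
        alpha[HME][idx] *= 2.0 ** fc
    taxa = [f"ASV{i + 1:04d}" for i in range(spec.n_taxa)]
    rows, sample_ids, groups = [], [], []
    for grp in (LME, HME):
        for j in range(spec.n_per_group):
            p = rng.dirichlet(alpha[grp])
            depth = max(1, rng.poisson(spec.depth_mean))
            rows.append(rng.multinomial(depth, p))
            sample_ids.append(f"{grp}_{j + 1:03d}")
            groups.append(grp)
    counts = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=taxa)
    table = ASVTable(
        counts=counts,
        groups=pd.Series(groups, index=sample_ids, name="group"),
        lineages=pd.Series({t: _lineage(i) for i, t in enumerate(taxa)}, name="lineage"),
    )
    truth = pd.DataFrame(
        [
            {"taxon": taxa[idx], "log2fc": fc, "side": HME if fc > 0 else LME}
            for idx, fc in spec.spiked_taxa
        ],
        columns=["taxon", "log2fc", "side"],
    )
    return table, truth


def make_ko_reference(spec: FunctionSimSpec, seed: int | None = None):
    """Deterministic KO lengths and KO -> level-3 -> level-2 mapping."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    kos = [f"K{i + 1:05d}" for i in range(spec.n_kos)]
    lengths = pd.Series(rng.integers(500, 3000, spec.n_kos).astype(float),
                        index=kos, name="length_bp")
    n_l3 = int(np.ceil(spec.n_kos / spec.kos_per_pathway))
    mapping = pd.DataFrame(
        {
            "KO": kos,
            "level3": [f"ko3_{i // spec.kos_per_pathway:03d}" for i in range(spec.n_kos)],
        }
    )
    mapping["level2"] = [
        f"L2_{int(l3.split('_')[1]) // spec.level3_per_level2:02d}"
        for l3 in mapping["level3"]
    ]
    assert mapping["level3"].nunique() == n_l3
    return lengths, mapping


def simulate_function_table(
    spec: FunctionSimSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.DataFrame]:
    """KO counts with pathway-level group effects.

    Per sample, KO counts ~ Poisson(depth * rate_k * gamma noise), with
    rates of KOs in affected level-3 pathways multiplied by 2**log2FC in
    the HME group. Returns (counts samples x KOs, lengths, mapping, truth).
    """
    rng = np.random.default_rng(spec.seed)
    lengths, mapping = make_ko_reference(spec)
    kos = list(lengths.index)
    base_rate = 1.0 / np.arange(1, spec.n_kos + 1, dtype=float) ** 0.5
    base_rate /= base_rate.sum()
    l3_of = mapping.set_index("KO")["level3"]
    mult = {LME: np.ones(spec.n_kos), HME: np.ones(spec.n_kos)}
    l3_names = sorted(mapping["level3"].unique())
    truth_rows = []
    for l3_idx, fc in spec.effect_pathways:
        name = l3_names[l3_idx]
        mask = (l3_of.loc[kos] == name).to_numpy()
        mult[HME][mask] *= 2.0 ** fc
        truth_rows.append({"pathway": name, "log2fc": fc,
                           "side": HME if fc > 0 else LME})
    shape = 1.0 / spec.dispersion ** 2
    rows, sample_ids, groups = [], [], []
    for grp in (LME, HME):
        rate = base_rate * mult[grp]
        rate = rate / rate.sum()
        for j in range(spec.n_per_group):
            lam = spec.depth_mean * rate * rng.gamma(shape, 1.0 / shape, spec.n_kos)
            rows.append(rng.poisson(lam))
            sample_ids.append(f"{grp}_{j + 1:03d}")
            groups.append(grp)
    counts = pd.DataFrame(np.asarray(rows, dtype=np.int64), index=sample_ids,
                          columns=kos)
    counts.attrs["groups"] = pd.Series(groups, index=sample_ids, name="group")
    truth = pd.DataFrame(truth_rows, columns=["pathway", "log2fc", "side"])
    return counts, lengths, mapping, truth
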