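"""Predicted-function (KEGG-ortholog) profiling: RPKM normalization,
pathway aggregation and LEfSe-style pathway screening.

RPKM of predicted KO abundances is a convention, not a physical quantity:
"reads" here are predicted KO counts, the length is a KO's reference gene
length (bp, supplied via a mapping file), and the library size is the
per-sample KO total. Pathway screening then runs on the RPKM values
directly, without the per-million rescaling used for taxa; the
conventional pathway thresholds are log10(LDA) > 1 (or > 2 for a stricter
report) with FDR < 0.05.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd

from .diffabund import screen_rank_table

UNMAPPED = "unmapped"


def rpkm_normalize(counts: pd.DataFrame, lengths_bp: pd.Series,
                   library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million: count * 1e9 / (length_bp * library).

    `counts` is samples x KOs; `lengths_bp` maps each KO to its reference
    gene length; `library_sizes` defaults to per-sample KO totals.
    """
    missing = counts.columns.difference(lengths_bp.index)
    if len(missing):
        raise ValueError(f"lengths missing for KOs: {list(missing)[:5]}")
    lens = lengths_bp.loc[counts.columns].astype(float)
    if (lens <= 0).any():
        raise ValueError("lengths must be positive")
    lib = counts.sum(axis=1).astype(float) if library_sizes is None \
        else pd.Series(library_sizes).loc[counts.index].astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return counts.astype(float).mul(1e9).div(lens, axis=1).div(lib, axis=0)


def aggregate_pathways(ko_table: pd.DataFrame, mapping: pd.DataFrame,
                       level: int = 3) -> pd.DataFrame:
    """Sum KO abundances into level-2 or level-3 KEGG pathways.

    `mapping` has columns KO, level3, level2 and may list a KO under
    several pathways: such a KO contributes its full abundance to each
    (deliberate double counting, the common practice for KEGG rollups).
    KOs absent from the mapping pool into 'unmapped'.
    """
    if level not in (2, 3):
        raise ValueError("level must be 2 or 3")
    col = f"level{level}"
    if not {"KO", col} <= set(mapping.columns):
        raise ValueError(f"mapping needs columns 'KO' and '{col}'")
    m = mapping[["KO", col]].dropna().drop_duplicates()
    out = {}
    mapped_kos: set[str] = set()
    for pathway, kos in m.groupby(col)["KO"]:
        present = ko_table.columns.intersection(kos)
        if len(present):
            out[pathway] = ko_table[present].sum(axis=1)
            mapped_kos.update(present)
    unmapped = ko_table.columns.difference(sorted(mapped_kos))
    if len(unmapped):
        warnings.warn(f"{len(unmapped)} KOs not in mapping; pooled into '{UNMAPPED}'")
        out[UNMAPPED] = ko_table[unmapped].sum(axis=1)
    if not out:
        raise ValueError("no pathways produced")
    return pd.DataFrame(out)


def pathway_screen(pathway_table: pd.DataFrame, groups: pd.Series,
                   lda_min: float = 1.0, alpha: float = 0.05,
                   bootstrap: int = 0, seed: int = 0,
                   level_label: str = "pathway") -> pd.DataFrame:
    """Differential pathways between two groups on RPKM-scale abundances.

    Same Kruskal-Wallis + BH-FDR + LDA-effect machinery as the taxon
    screen, but run on the supplied (already RPKM-normalized) values with
    no per-million rescaling.
    """
    g = pd.Series(groups).loc[pathway_table.index]
    return screen_rank_table(pathway_table, g, level_label, lda_min, alpha,
                             bootstrap=bootstrap, seed=seed)
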