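"""End-to-end orchestration: simulate -> phenotype -> select -> diversity
-> lefse -> functions, with a JSON manifest for reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, community, diffabund, functions, io as ch4io, phenotyping, simulate


@dataclass
class PipelineConfig:
    """Paths, thresholds and the global seed for a full run.

    When the three input blocks (traces/meta, ASV files, KO files) are
    left as None the synthetic generator produces them under `seed`.
    """

    outdir: str = "ch4_out"
    seed: int = 0
    # inputs (None -> simulate)
    traces: str | None = None
    cow_meta: str | None = None
    asv_table: str | None = None
    taxonomy: str | None = None
    group_map: str | None = None
    tree: str | None = None
    ko_table: str | None = None
    ko_lengths: str | None = None
    kegg_map: str | None = None
    # thresholds
    range_lo: float = 200.0
    range_hi: float = 8000.0
    min_sessions: int = 2
    qc_k: float = 3.0
    select_k: float = 0.65
    milk_lo: float = 30.0
    milk_hi: float = 40.0
    parities: tuple[int, ...] = (1, 2)
    min_asv_total: int = 5
    beta_metric: str = "braycurtis"
    n_perm: int = 999
    lda_min_taxa: float = 3.0
    lda_min_pathway: float = 1.0
    fdr_alpha: float = 0.05
    top_k: int = 10
    pathway_level: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ch4io.InputFormatError(f"unknown config keys: {sorted(unknown)}")
        if "parities" in data:
            data["parities"] = tuple(data["parities"])
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; returns (and writes) the manifest.

    Each stage records its outputs, row counts and file checksums; any
    failure aborts with the stage name attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "version": __version__}
    manifest: dict = {
        "tool": f"ch4rumen v{__version__}",
        "seed": config.seed,
        "thresholds": {
            k: v for k, v in asdict(config).items()
            if isinstance(v, (int, float, tuple)) and k != "seed"
        },
        "stages": [],
    }

    def record(stage: str, files: dict, **info):
        manifest["stages"].append(
            {
                "stage": stage,
                "files": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                          for k, p in files.items()},
                **info,
            }
        )

    # --- stage 1: simulate (or locate inputs)
    stage = "simulate"
    try:
        rng_seed = int(config.seed)
        if config.traces is None:
            sessions, latent = simulate.simulate_lmd_sessions(
                simulate.TraceSimSpec(seed=rng_seed)
            )
            traces_path = out / "traces.csv"
            ch4io.write_trace_csv(traces_path, sessions, meta)
            n_cows = latent.size
            rng = np.random.default_rng(rng_seed + 1)
            cow_meta = pd.DataFrame(
                {
                    "parity": rng.integers(1, 4, n_cows),
                    "milk_yield": rng.uniform(25, 45, n_cows).round(1),
                    "dim": rng.integers(50, 250, n_cows),
                },
                index=latent.index,
            )
            cow_meta.index.name = "cow_id"
            meta_path = out / "cow_meta.tsv"
            ch4io.write_cow_metadata(meta_path, cow_meta, meta)
        else:
            traces_path = Path(config.traces)
            meta_path = Path(config.cow_meta)
            for p in (traces_path, meta_path):
                if not p.exists():
                    raise FileNotFoundError(p)
        if config.asv_table is None:
            spec = simulate.CommunitySimSpec(
                seed=rng_seed + 2,
                spiked_taxa=((4, 1.5), (9, -1.5)),
            )
            table, truth = simulate.simulate_asv_table(spec)
            asv_path, tax_path, grp_path = (out / "asv.tsv", out / "tax.tsv",
                                            out / "groups.tsv")
            ch4io.write_asv_table(asv_path, table, meta)
            ch4io.write_taxonomy(tax_path, table.lineages, meta)
            ch4io.write_group_map(grp_path, table.groups, meta)
            truth.to_csv(out / "asv_truth.tsv", sep="\t", index=False)
        else:
            asv_path, tax_path, grp_path = (Path(config.asv_table),
                                            Path(config.taxonomy),
                                            Path(config.group_map))
        if config.ko_table is None:
            fspec = simulate.FunctionSimSpec(seed=rng_seed + 3,
                                             effect_pathways=((2, 1.0),))
            ko_counts, ko_lens, kmap, ftruth = simulate.simulate_function_table(fspec)
            ko_path, len_path, map_path = (out / "ko.tsv", out / "ko_lengths.tsv",
                                           out / "kegg_map.tsv")
            ch4io.write_ko_table(ko_path, ko_counts, meta)
            ch4io.write_ko_lengths(len_path, ko_lens, meta)
            ch4io.write_kegg_map(map_path, kmap, meta)
            ftruth.to_csv(out / "ko_truth.tsv", sep="\t", index=False)
        else:
            ko_path, len_path, map_path = (Path(config.ko_table),
                                           Path(config.ko_lengths),
                                           Path(config.kegg_map))
        record(stage, {"traces": traces_path, "asv": asv_path, "ko": ko_path})
    except Exception as e:  # noqa: BLE001 - per-stage context propagation
        raise StageError(stage, e) from e

    # --- stage 2: phenotype
    stage = "phenotype"
    try:
        sessions, report = ch4io.parse_trace_csv(traces_path)
        cows = phenotyping.phenotype_cows(
            sessions, lo=config.range_lo, hi=config.range_hi,
            min_sessions=config.min_sessions, qc_k=config.qc_k,
        )
        phen_path = out / "phenotypes.tsv"
        ch4io.write_phenotypes(phen_path, cows, meta)
        record(stage, {"phenotypes": phen_path}, n_cows=int(len(cows)),
               n_qc_pass=int(cows["qc_pass"].sum()), trace_report=report)
    except Exception as e:
        raise StageError(stage, e) from e

    # --- stage 3: select groups
    stage = "select"
    try:
        cow_meta_df = ch4io.read_cow_metadata(meta_path)
        merged = cows[cows["qc_pass"]].join(cow_meta_df, how="inner")
        selected = phenotyping.select_groups(
            merged, k=config.select_k, milk_lo=config.milk_lo,
            milk_hi=config.milk_hi, parities=set(config.parities),
        )
        sel_path = out / "groups_selected.tsv"
        ch4io.write_phenotypes(sel_path, selected, meta)
        n_lme = int((selected["group"] == phenotyping.LME).sum())
        n_hme = int((selected["group"] == phenotyping.HME).sum())
        record(stage, {"selected": sel_path}, n_lme=n_lme, n_hme=n_hme)
    except Exception as e:
        raise StageError(stage, e) from e

    # --- stage 4: diversity
    stage = "diversity"
    try:
        table = ch4io.read_asv_table(asv_path, tax_path, grp_path)
        table = community.filter_low_count_asvs(table, config.min_asv_total)
        alpha = community.alpha_diversity_table(table)
        alpha_path = out / "alpha.tsv"
        with open(alpha_path, "w", encoding="utf-8") as fh:
            fh.write("".join(f"## {k}={v}\n" for k, v in meta.items()))
            alpha.rename_axis("sample_id").to_csv(fh, sep="\t")
        if config.beta_metric == "unifrac":
            if config.tree is None:
                raise ch4io.InputFormatError("unifrac requested but no tree given")
            dm = community.unweighted_unifrac(table, ch4io.read_tree(config.tree))
        else:
            dm = community.bray_curtis(table)
        ord_res = community.pcoa(dm, n_axes=2)
        nmds_res = community.nmds(dm, seed=config.seed)
        perm = community.permanova(dm, table.groups, n_perm=config.n_perm,
                                   seed=config.seed)
        venn = community.venn_partition(table)
        beta_path = out / "beta_summary.json"
        beta_path.write_text(json.dumps(
            {
                "metric": config.beta_metric,
                "pco1_percent": float(ord_res.proportion_explained[0] * 100),
                "nmds_stress": nmds_res.stress,
                "permanova": {"F": perm.f, "R2": perm.r2, "p": perm.p},
                "venn": venn._asdict(),
            }, indent=2))
        record(stage, {"alpha": alpha_path, "beta": beta_path},
               n_features=len(table.feature_ids))
    except Exception as e:
        raise StageError(stage, e) from e

    # --- stage 5: lefse
    stage = "lefse"
    try:
        effects = diffabund.lefse_screen(
            table, lda_min=config.lda_min_taxa, alpha=config.fdr_alpha,
            seed=config.seed,
        )
        eff_path = out / "effects.tsv"
        ch4io.write_effects(eff_path, effects, meta)
        nets = diffabund.spearman_network(table, top_k=min(config.top_k,
                                                           len(table.feature_ids)))
        net_path = out / "networks.json"
        net_path.write_text(json.dumps(
            {g: {"taxa": n.taxa, "rho": n.rho.round(4).to_dict()}
             for g, n in nets.items()}, indent=2))
        record(stage, {"effects": eff_path, "networks": net_path},
               n_pass=int(effects["pass"].sum()))
    except Exception as e:
        raise StageError(stage, e) from e

    # --- stage 6: functions
    stage = "functions"
    try:
        ko_counts = ch4io.read_ko_table(ko_path)
        lens = ch4io.read_ko_lengths(len_path)
        kmap = ch4io.read_kegg_map(map_path)
        groups = ch4io.read_group_map(grp_path)
        rpkm = functions.rpkm_normalize(ko_counts, lens)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pw = functions.aggregate_pathways(rpkm, kmap, level=config.pathway_level)
        common = pw.index.intersection(groups.index)
        pw_eff = functions.pathway_screen(
            pw.loc[common], groups.loc[common], lda_min=config.lda_min_pathway,
            alpha=config.fdr_alpha, seed=config.seed,
            level_label=f"level{config.pathway_level}",
        )
        pw_path = out / "pathways.tsv"
        ch4io.write_effects(pw_path, pw_eff, meta)
        record(stage, {"pathways": pw_path}, n_pass=int(pw_eff["pass"].sum()))
    except Exception as e:
        raise StageError(stage, e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
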