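"""Species-level orchestration: from CDS records to the full bundle of
composition, index and diagnostic tables, plus multi-species comparison."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import composition as comp_mod
from . import cub_indices as cub_mod
from . import selection_analysis as sel_mod
from .cds_io import CdsRecord, CodonCounts, count_codons, pooled_counts, read_cds_fasta
from .genetic_code import GeneticCode, build_standard_code

logger = logging.getLogger(__name__)

#: Defaults mirroring the analysis conventions; all overridable per run.
DEFAULT_MIN_CODONS = 30
DEFAULT_N_PERM = 5000


@dataclass
class SpeciesBundle:
    """Everything one species' analysis produces."""

    label: str
    counts: list[CodonCounts]
    composition: pd.DataFrame
    comp_records: list[comp_mod.CompositionRecord]
    cub: pd.DataFrame
    cub_records: list[cub_mod.CUBRecord]
    pooled_composition: comp_mod.CompositionRecord
    species_rscu: cub_mod.RSCUTable
    preferred: cub_mod.PreferredCodons
    weights: cub_mod.CaiWeights
    optimal: tuple[str, ...]
    neutrality: sel_mod.NeutralityFit
    deviation: sel_mod.DeviationSummary
    strength: sel_mod.EncStrengthSummary
    pr2_quadrants: dict[str, int]
    cai_enc: pd.DataFrame
    cai_enc_rho: float
    cai_enc_p: float
    permutation: pd.DataFrame | None
    config: dict = field(default_factory=dict)


def analyze_records(
    records: list[CdsRecord],
    code: GeneticCode | None = None,
    label: str = "species",
    min_codons: int = DEFAULT_MIN_CODONS,
    cai_reference: list[CodonCounts] | None = None,
    pr2_site_set: str = comp_mod.ALL_SYNONYMOUS,
    optimal: set[str] | None = None,
    n_perm: int = 0,
    seed: int = 0,
    drop_terminal_stop: bool = True,
) -> SpeciesBundle:
    """Run the full single-species analysis on validated CDS records.

    ``cai_reference=None`` uses the self-referential reference (the 5% of
    genes with lowest ENC); ``optimal=None`` takes the preferred codons of
    the species-pooled RSCU.  ``n_perm > 0`` adds the per-gene synonymous
    permutation null (seed-deterministic, order-invariant).
    """
    code = code or build_standard_code()
    counts = [count_codons(r, code, drop_terminal_stop) for r in records]
    kept = [c for c in counts if c.total_codons >= min_codons]
    n_short = len(counts) - len(kept)
    if n_short:
        logger.info(
            "%s: %d genes below %d codons excluded from index computation",
            label, n_short, min_codons,
        )
    if not kept:
        raise ValueError(f"{label}: no genes with >= {min_codons} codons")

    comp_records = [
        comp_mod.composition_record(c, code, pr2_site_set) for c in kept
    ]
    comp_df = comp_mod.composition_table(comp_records)

    pooled = pooled_counts(kept, label)
    pooled_comp = comp_mod.composition_record(pooled, code, pr2_site_set)
    species_rscu = cub_mod.rscu(pooled, code)
    preferred = cub_mod.preferred_codons(species_rscu)

    if cai_reference is None:
        reference, ref_desc = cub_mod.select_reference_by_enc(kept, code)
    else:
        reference, ref_desc = cai_reference, "user-supplied reference set"
    weights = cub_mod.cai_weights(reference, code, ref_desc)

    if optimal is None:
        optimal_t = preferred.codons or cub_mod.preferred_codons(species_rscu).codons
        if not optimal_t:  # perfectly uniform usage: fall back to family firsts
            optimal_t = tuple(
                fam[0] for fam in code.synonymous_families.values()
            )
        optimal_desc = "preferred codons of species-pooled RSCU"
    else:
        optimal_t = tuple(sorted(optimal))
        optimal_desc = "user-supplied optimal set"

    cub_records = [
        cub_mod.cub_record(c, code, weights, set(optimal_t), rec.gc3s)
        for c, rec in zip(kept, comp_records)
    ]
    cub_df = pd.DataFrame([vars(r) for r in cub_records]).set_index("gene_id")

    neut = sel_mod.neutrality_fit(comp_records)
    deviation = sel_mod.enc_deviation_summary(cub_records)
    strength = sel_mod.classify_enc_strength(cub_records)
    quadrants = sel_mod.pr2_quadrant_summary(comp_records)
    cai_enc_df, rho, rho_p = sel_mod.cai_enc_table(cub_records)

    perm_df = None
    if n_perm > 0:
        rows = []
        for c in kept:
            try:
                null = sel_mod.permutation_null(c, code, n_perm=n_perm, seed=seed)
            except ValueError:
                continue
            rows.append((c.gene_id, null.observed_ratio, null.p_value))
        perm_df = pd.DataFrame(
            rows, columns=["gene_id", "deviation_ratio", "perm_p"]
        ).set_index("gene_id")

    config = {
        "label": label,
        "min_codons": min_codons,
        "drop_terminal_stop": drop_terminal_stop,
        "pr2_site_set": pr2_site_set,
        "cai_reference": ref_desc,
        "optimal_set": list(optimal_t),
        "optimal_set_source": optimal_desc,
        "n_perm": n_perm,
        "seed": seed,
        "n_genes_analyzed": len(kept),
        "n_genes_below_min_codons": n_short,
        "thresholds": {
            "enc_strong_below": sel_mod.ENC_STRONG_BELOW,
            "enc_weak_above": sel_mod.ENC_WEAK_ABOVE,
            "rscu_preferred_above": 1.0,
            "deviation_bin_edges": list(sel_mod.DEVIATION_BIN_EDGES),
        },
    }
    return SpeciesBundle(
        label=label,
        counts=kept,
        composition=comp_df,
        comp_records=comp_records,
        cub=cub_df,
        cub_records=cub_records,
        pooled_composition=pooled_comp,
        species_rscu=species_rscu,
        preferred=preferred,
        weights=weights,
        optimal=optimal_t,
        neutrality=neut,
        deviation=deviation,
        strength=strength,
        pr2_quadrants=quadrants,
        cai_enc=cai_enc_df,
        cai_enc_rho=rho,
        cai_enc_p=rho_p,
        permutation=perm_df,
        config=config,
    )


def analyze_fasta(path: str | Path, label: str | None = None, **kwargs) -> SpeciesBundle:
    """Read a CDS FASTA and run :func:`analyze_records` on it."""
    result = read_cds_fasta(path)
    label = label or Path(path).stem
    bundle = analyze_records(result.records, label=label, **kwargs)
    bundle.config["input"] = str(path)
    bundle.config["read_summary"] = result.summary
    return bundle


def gc_correlation_panel(bundle: SpeciesBundle) -> pd.DataFrame:
    """Pairwise Pearson correlations among GC1/GC2/GC3/GCall across genes."""
    cols = ["gc1", "gc2", "gc3", "gc_all"]
    sub = bundle.composition[cols]
    out = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r, p = stats.pearsonr(sub[a], sub[b])
            out.append((bundle.label, a, b, float(r), float(p)))
    return pd.DataFrame(out, columns=["species", "x", "y", "pearson_r", "p_value"])


def compare_bundles(bundles: list[SpeciesBundle]) -> dict:
    """Cross-species report: GC correlation panel, RSCU heatmap matrix and
    the preferred-codon comparison."""
    if len(bundles) < 2:
        raise ValueError("comparison requires at least two species bundles")
    labels = [b.label for b in bundles]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate species labels: {labels}")
    code = build_standard_code()
    heat_values, heat_marks = sel_mod.rscu_heatmap_matrix(
        [b.species_rscu for b in bundles], code
    )
    preferred = pd.DataFrame(
        {
            b.label: {
                "n_preferred": b.preferred.count,
                **{
                    f"ending_{k}": v
                    for k, v in b.preferred.ending_base_tally.items()
                },
            }
            for b in bundles
        }
    ).T
    membership = pd.DataFrame(
        {
            b.label: {c: c in b.preferred.codons for c in code.analysis_codons}
            for b in bundles
        }
    )
    gc_panel = pd.concat([gc_correlation_panel(b) for b in bundles], ignore_index=True)
    return {
        "heatmap_values": heat_values,
        "heatmap_marks": heat_marks,
        "preferred_summary": preferred,
        "preferred_membership": membership,
        "gc_correlation_panel": gc_panel,
    }


# ---------------------------------------------------------------------------
# serialization

def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_bundle(bundle: SpeciesBundle, outdir: str | Path, decimals: int = 2) -> None:
    """Write the species bundle as TSV/JSON files.

    Full-precision tables are written alongside 2-decimal report variants
    that mirror the published table formatting.  The run config is
    serialized so any run is reproducible from its output directory alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.composition.to_csv(outdir / "composition.tsv", sep="\t")
    bundle.cub.to_csv(outdir / "cub_indices.tsv", sep="\t")
    rscu_series = pd.Series(bundle.species_rscu.rscu, name=bundle.label)
    rscu_series.rename_axis("codon").to_csv(outdir / "rscu_species.tsv", sep="\t")
    sel_mod.neutrality_table(bundle.comp_records).to_csv(
        outdir / "neutrality.tsv", sep="\t"
    )
    sel_mod.pr2_table(bundle.comp_records).to_csv(outdir / "pr2.tsv", sep="\t")
    bundle.cai_enc.to_csv(outdir / "cai_enc.tsv", sep="\t")
    bundle.deviation.to_frame(decimals=decimals).to_csv(
        outdir / "deviation_histogram.tsv", sep="\t"
    )
    bundle.strength.to_frame().to_csv(
        outdir / "enc_strength.tsv", sep="\t", index=False
    )
    comp_mod.species_gc_summary(
        bundle.composition, bundle.pooled_composition, bundle.label
    ).round(decimals).to_csv(outdir / "gc_summary.tsv", sep="\t")
    if bundle.permutation is not None:
        bundle.permutation.to_csv(outdir / "permutation_null.tsv", sep="\t")
    summary = {
        "label": bundle.label,
        "preferred_codons": {
            "codons": list(bundle.preferred.codons),
            "count": bundle.preferred.count,
            "ending_base_tally": bundle.preferred.ending_base_tally,
        },
        "neutrality_fit": vars(bundle.neutrality),
        "pr2_quadrants": bundle.pr2_quadrants,
        "enc_strength": vars(bundle.strength),
        "cai_enc_spearman": {"rho": bundle.cai_enc_rho, "p": bundle.cai_enc_p},
        "mean_enc": float(bundle.cub["enc_obs"].mean()),
        "mean_cai": float(bundle.cub["cai"].mean()),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)
    with open(outdir / "config.json", "w") as fh:
        json.dump(bundle.config, fh, indent=1, sort_keys=True, default=_json_default)


def write_comparison(report: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report["heatmap_values"].to_csv(outdir / "rscu_heatmap_matrix.tsv", sep="\t")
    report["heatmap_marks"].to_csv(outdir / "rscu_heatmap_marks.tsv", sep="\t")
    report["preferred_summary"].to_csv(outdir / "preferred_summary.tsv", sep="\t")
    report["preferred_membership"].to_csv(
        outdir / "preferred_membership.tsv", sep="\t"
    )
    report["gc_correlation_panel"].to_csv(
        outdir / "gc_correlation_panel.tsv", sep="\t", index=False
    )
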