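"""End-to-end orchestration: simulate -> quant -> stats -> map -> coloc -> causal.

Every stage writes TSV artifacts into the run directory and appends counts
and thresholds to the run log, so any reported number is auditable.  With a
fixed config (including the seed) the outputs are bit-for-bit reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import causal as causal_mod
from . import coloc as coloc_mod
from . import expression, qtl, tmt
from . import io as rio
from . import sim
from .containers import GenotypeMatrix, ProteinMatrix

__all__ = ["run_pipeline", "summary_stats_window"]


def summary_stats_window(
    y: pd.Series,
    genotypes: GenotypeMatrix,
    K: pd.DataFrame,
    chrom: str,
    start_bp: float,
    end_bp: float,
) -> pd.DataFrame:
    """Per-marker (beta, se) summary statistics for one trait in a window."""
    markers = genotypes.markers_in_window(chrom, start_bp, end_bp)
    if not markers:
        raise ValueError("window contains no markers")
    sub = GenotypeMatrix(genotypes.dosage[markers], genotypes.marker_map.loc[markers])
    scan = qtl.lmm_scan(y, sub, K)
    return scan[["beta", "se", "p", "chrom", "pos_bp"]]


def _stage_on(config, name: str) -> bool:
    return name in config.stages


def run_pipeline(config: "rio.RunConfig") -> "rio.RunLog":
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = rio.RunLog()
    log.add("config", seed=config.seed, stages=",".join(config.stages))

    # ------------------------------------------------------------- simulate
    genotypes = sim.simulate_ri_genotypes(config.sim)
    proteome, truth = sim.simulate_proteome(genotypes, config.sim)
    psms, impurity = sim.simulate_psms(proteome, config.sim)
    trait_sim = sim.simulate_trait(genotypes, proteome, truth, config.trait_model, config.sim)
    if _stage_on(config, "simulate"):
        rio.write_geno(genotypes, out / "genotypes.geno")
        rio.write_protein_matrix(proteome, out / "proteome_true.tsv", out / "samples.tsv")
        rio.write_psm_table(psms, out / "psms.tsv", out / "samples.tsv")
        rio.write_annotation(truth.annotation, out / "annotation.tsv")
        rio.write_impurity(impurity, out / "impurity")
        trait_sim.trait.to_csv(out / "trait.tsv", sep="\t", header=True)
        gt = pd.DataFrame(
            {"cis_marker": pd.Series(truth.cis_assignments),
             "cis_beta": pd.Series(truth.cis_beta)}
        )
        gt.to_csv(out / "ground_truth_cis.tsv", sep="\t", index_label="protein")
        log.add("simulate", n_strains=genotypes.n_strains, n_markers=genotypes.n_markers,
                n_proteins=len(proteome.proteins), n_psms=len(psms.data))

    # ---------------------------------------------------------------- quant
    quant = tmt.quantify(
        psms, impurity, min_intensity=config.min_intensity,
        min_median=config.min_median, trim_fraction=config.trim_fraction,
    ) if _stage_on(config, "quant") else proteome
    if _stage_on(config, "quant"):
        rio.write_protein_matrix(quant, out / "proteome_quant.tsv", out / "samples.tsv")
        log.add("quant", n_proteins=len(quant.proteins),
                min_intensity=config.min_intensity, min_median=config.min_median)

    # ---------------------------------------------------------------- stats
    if _stage_on(config, "stats"):
        founders = [s for s in ("SHR", "BN-Lx") if s in set(quant.samples["strain"])]
        if len(founders) == 2:
            a = list(quant.samples.index[quant.samples["strain"] == founders[0]])
            b = list(quant.samples.index[quant.samples["strain"] == founders[1]])
            de = expression.moderated_de(quant, a, b,
                                         adj_p_cut=config.adj_p_cut, lfc_cut=config.lfc_cut)
            de.table.to_csv(out / "de.tsv", sep="\t", index_label="protein")
            log.add("stats_de", n_de=de.n_de, adj_p_cut=config.adj_p_cut, lfc_cut=config.lfc_cut)
        h2 = expression.heritability(quant)
        h2.to_csv(out / "heritability.tsv", sep="\t", index_label="protein")
        cv = expression.cv_flag(quant)
        cv.to_csv(out / "cv.tsv", sep="\t", index_label="protein")
        sexes = expression.paired_sex_test(quant)
        sexes.to_csv(out / "sex_test.tsv", sep="\t", index_label="protein")
        log.add("stats", median_h2=float(h2["h2"].median()),
                n_highly_variable=int(cv["is_highly_variable"].sum()),
                n_sex_different=sexes.attrs["n_below"])

    # ------------------------------------------------------------------ map
    results = None
    K = qtl.kinship(genotypes)
    if _stage_on(config, "map"):
        model = qtl.ProteomeQTLModel(quant, genotypes, truth.annotation, K=K)
        results = model.fit(n_perm=config.n_perm, target_fdr=config.target_fdr,
                            seed=config.seed, cis_window_bp=config.cis_window_bp)
        results.records.to_csv(out / "qtl_records.tsv", sep="\t")
        s = results.summary().iloc[0]
        log.add("map", n_cis_significant=int(s["n_cis_significant"]),
                n_trans_significant=int(s["n_trans_significant"]),
                cis_p_threshold=float(s["cis_p_threshold"]),
                genome_p_threshold=float(s["genome_p_threshold"]))

    # ---------------------------------------------------------------- coloc
    if _stage_on(config, "coloc") and results is not None:
        rows = []
        sm = quant.strain_means()
        trans = results.trans_calls()
        cis = results.cis_calls()
        for t_id, t_rec in trans.iterrows():
            near = cis[(cis["chrom"] == t_rec["chrom"])
                       & (abs(cis["pos_bp"] - t_rec["pos_bp"]) <= config.flank_bp)]
            for c_id, c_rec in near.iterrows():
                lo, hi = coloc_mod.make_window(t_rec["pos_bp"], config.flank_bp)
                try:
                    s1 = summary_stats_window(sm.loc[t_id], genotypes, K, t_rec["chrom"], lo, hi)
                    s2 = summary_stats_window(sm.loc[c_id], genotypes, K, t_rec["chrom"], lo, hi)
                    res = coloc_mod.coloc_posterior(s1, s2, p1=config.p1, p2=config.p2,
                                                    p12=config.p12, pp4_cut=config.pp4_cut,
                                                    window=(t_rec["chrom"], lo, hi))
                except ValueError:
                    continue
                rows.append({"trans_trait": t_id, "cis_trait": c_id, "chrom": t_rec["chrom"],
                             "start": lo, "end": hi, **dict(zip(
                                 ["pp0", "pp1", "pp2", "pp3", "pp4"], res.pp)),
                             "call": res.call})
        pd.DataFrame(rows).to_csv(out / "coloc.tsv", sep="\t", index=False)
        log.add("coloc", n_pairs=len(rows), n_colocalized=sum(r["call"] for r in rows))

    # --------------------------------------------------------------- causal
    if _stage_on(config, "causal"):
        strains = trait_sim.trait.index
        q = genotypes.dosage.loc[strains, trait_sim.anchor_marker].to_numpy()
        source = trait_sim.protein if config.trait_model == "reactive" else quant
        means = source.strain_means()
        if trait_sim.anchor_protein in means.index:
            p_vals = means.loc[trait_sim.anchor_protein, strains].to_numpy()
            fit = causal_mod.select_model(
                causal_mod.TripletData(q, p_vals, trait_sim.trait.to_numpy())
            )
            fit.summary().to_csv(out / "causal.tsv", sep="\t", index_label="model")
            log.add("causal", generating_model=config.trait_model, selected=fit.best,
                    delta_bic=round(fit.delta, 4), mediation=round(fit.mediation, 4)
                    if np.isfinite(fit.mediation) else "nan")

    log.write(out / "run_log.tsv")
    return log
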