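"""Synthetic recombinant-inbred (RI) panel generator with known ground truth.

Emulates a two-founder, sib-mated RI family of the HXB/BXH kind: fully inbred
strains whose genomes are fixed mosaics of the two founder haplotypes, typed
at a grid of biallelic markers, profiled by multiplexed TMT proteomics in
several batches with one male and one female sample per strain, and scored on
strain-level traits generated under explicit causal models.

Every downstream stage of the package (quantification, descriptive genetics,
QTL mapping, colocalization, causal inference) can be validated against the
ground truth this module plants.

Randomness
----------
All draws flow from ``SimConfig.seed`` through ``numpy`` ``SeedSequence``
spawning with a fixed stream order: 0 genotypes, 1 proteome, 2 PSMs, 3 trait.
Identical configs therefore give bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ProteinMatrix, PSMTable

__all__ = [
    "SimConfig",
    "GroundTruth",
    "TraitSim",
    "haldane_recombination",
    "ri_expansion",
    "simulate_ri_genotypes",
    "simulate_proteome",
    "simulate_psms",
    "simulate_trait",
    "build_impurity_matrix",
]

#: Fixed physical scaling of the genetic map: 1 cM = 2 Mb.  Chosen once so
#: that cis windows stated in bp are meaningful on the simulated map.
BP_PER_CM = 2_000_000

TRAIT_MODELS = ("causal", "reactive", "pleiotropic", "null")


@dataclass
class SimConfig:
    """Parameters of the simulated RI study.

    Defaults mirror the design of a deep rat RI brain-proteome study:
    29 RI strains plus two founders, two samples (M/F) per strain, five TMT
    batches, markers on a 20-chromosome map, a median strain-mean
    heritability target of 0.54, and planted cis effects of 1 log2 unit.
    The protein count defaults to 500: a deliberately down-scaled panel that
    keeps whole-pipeline simulations cheap while leaving every estimator's
    behaviour unchanged.
    """

    n_strains: int = 29                  # RI strains; two founders are appended
    n_chromosomes: int = 20
    markers_per_chr: int = 50
    chr_length_cM: float = 50.0
    cross_type: str = "sib-mating"       # or "selfing"
    n_proteins: int = 500
    n_cis_effects: int = 50
    cis_effect_size: float = 1.0         # log2 units per founder-allele dose
    n_trans_effects: int = 10
    trans_effect_size: Optional[float] = None  # defaults to cis_effect_size
    polygenic_h2: float = 0.54           # target of the strain-mean estimator
    polygenic_sd: float = 0.25           # log2 sd of the kinship-structured term
    sex_effect_sd: float = 0.05          # log2 units
    n_batches: int = 5
    batch_effect_sd: float = 0.2         # log2 units
    psm_per_protein: int = 3
    psm_offset_sd: float = 1.0           # per-PSM ionisation offset, log2
    psm_noise_sd: float = 0.3            # log2 units
    channel_effect_sd: float = 0.2       # per-channel loading effect, log2
    impurity_spill: float = 0.05         # fraction of signal leaking to neighbours
    residual_sd: float = None            # overrides h2-derived residual noise
    baseline_mean: float = 20.0          # log2 intensity scale of the platform
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_strains": self.n_strains,
            "n_chromosomes": self.n_chromosomes,
            "markers_per_chr": self.markers_per_chr,
            "n_proteins": self.n_proteins,
            "n_batches": self.n_batches,
            "psm_per_protein": self.psm_per_protein,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a count >= 1, got {value!r}")
        if self.cross_type not in {"sib-mating", "selfing"}:
            raise ValueError(f"unknown cross_type {self.cross_type!r}")
        if not 0.0 <= self.polygenic_h2 <= 1.0:
            raise ValueError("polygenic_h2 must lie in [0, 1]")
        if not 0.0 <= self.impurity_spill:
            raise ValueError("impurity_spill must be >= 0")
        if self.impurity_spill >= 0.5:
            raise ValueError("impurity_spill >= 0.5 makes the mixing matrix non-diagonally-dominant")
        if self.n_cis_effects > self.n_proteins:
            raise ValueError("n_cis_effects exceeds n_proteins")
        for name in ("cis_effect_size", "polygenic_sd", "sex_effect_sd", "batch_effect_sd",
                     "psm_noise_sd", "psm_offset_sd", "channel_effect_sd"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.chr_length_cM < 0:
            raise ValueError("chr_length_cM must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Child generator for one of the documented streams."""
        seqs = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(seqs[stream])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    cis_assignments: dict            # protein -> marker id
    trans_assignments: dict          # protein -> list of marker ids
    true_h2: pd.Series               # realised strain-mean variance fraction
    annotation: pd.DataFrame         # protein, chrom, tss_bp, exon_start_bp, exon_end_bp
    cis_beta: dict = field(default_factory=dict)
    trans_beta: dict = field(default_factory=dict)
    trait_model: Optional[str] = None


@dataclass
class TraitSim:
    """A simulated strain-level trait and its generating structure."""

    trait: pd.Series                 # strain -> value
    model: str
    anchor_protein: str
    anchor_marker: str
    protein: ProteinMatrix           # possibly regenerated (reactive model)


# ---------------------------------------------------------------------------
# Genetic map helpers
# ---------------------------------------------------------------------------

def haldane_recombination(d_cM):
    """Per-meiosis recombination fraction for a map distance in cM.

    Haldane map function r = (1 - exp(-2d)) / 2 with d in Morgans.
    """
    d = np.asarray(d_cM, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def ri_expansion(r, cross_type: str = "sib-mating"):
    """Fixed-recombinant frequency R between adjacent loci in an RI panel.

    The repeated inbreeding generations give each recombination event several
    chances to fix, expanding the map: R = 4r/(1+6r) for sib-mating and
    R = 2r/(1+2r) for selfing.  R is nondecreasing in r and capped at 0.5.
    """
    r = np.asarray(r, dtype=float)
    if cross_type == "sib-mating":
        return 4.0 * r / (1.0 + 6.0 * r)
    if cross_type == "selfing":
        return 2.0 * r / (1.0 + 2.0 * r)
    raise ValueError(f"unknown cross_type {cross_type!r}")


def simulate_ri_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate fully inbred RI genotypes as a Markov chain along each chromosome.

    Each strain starts a chromosome with a fair coin flip between founder
    alleles and switches between adjacent markers with probability R(d).
    The two founders are appended as an all-0 and an all-1 row.
    """
    config.validate()
    rng = config.rng(0)
    n, m = config.n_strains, config.markers_per_chr

    names = [f"HXB{i + 1:02d}" for i in range(n)]
    marker_rows = []
    chrom_blocks = []
    for c in range(1, config.n_chromosomes + 1):
        if m > 1:
            cm = np.linspace(0.0, config.chr_length_cM, m)
        else:
            cm = np.array([config.chr_length_cM / 2.0])
        gaps = np.diff(cm)
        flip_p = ri_expansion(haldane_recombination(gaps), config.cross_type)

        state = rng.integers(0, 2, size=n)
        cols = [state.copy()]
        for p in flip_p:
            flips = rng.random(n) < p
            state = np.where(flips, 1 - state, state)
            cols.append(state.copy())
        chrom_blocks.append(np.column_stack(cols))
        for j in range(m):
            marker_rows.append(
                (f"c{c:02d}m{j + 1:03d}", str(c), int(round(cm[j] * BP_PER_CM)) + 1, float(cm[j]))
            )

    dosage = np.hstack(chrom_blocks).astype(float)
    # founders: all reference (0) and all alternative (1)
    dosage = np.vstack([dosage, np.zeros(dosage.shape[1]), np.ones(dosage.shape[1])])
    names = names + ["BN-Lx", "SHR"]

    marker_map = pd.DataFrame(
        marker_rows, columns=["marker", "chrom", "pos_bp", "cM"]
    ).set_index("marker")
    return GenotypeMatrix(pd.DataFrame(dosage, index=names, columns=marker_map.index), marker_map)


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def _chrom_length_bp(config: SimConfig) -> int:
    return int(round(config.chr_length_cM * BP_PER_CM)) + 1


def _kinship_for_sim(dosage: np.ndarray) -> np.ndarray:
    """Centered-relatedness kinship, normalised to unit mean diagonal."""
    x = dosage - dosage.mean(axis=0, keepdims=True)
    k = x @ x.T / dosage.shape[1]
    d = np.mean(np.diag(k))
    return k / d if d > 0 else k


def simulate_proteome(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[ProteinMatrix, GroundTruth]:
    """Simulate a log2 protein x sample matrix with planted genetic effects.

    Per-strain genetic value = beta_cis * dose + sum(beta_trans * dose) + a
    kinship-structured polygenic draw.  The strain value is copied to the two
    sex replicates, then sex, batch and residual effects are added at sample
    level.  The residual scale is solved per protein so the strain-mean
    heritability estimator targets ``polygenic_h2`` (see methods note), unless
    ``residual_sd`` overrides it.
    """
    config.validate()
    rng = config.rng(1)
    strains = genotypes.strains
    n_strains = len(strains)
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    markers = genotypes.marker_map

    prot_ids = [f"P{i + 1:04d}" for i in range(config.n_proteins)]

    if config.n_cis_effects > genotypes.n_markers:
        raise ValueError("n_cis_effects exceeds available markers")

    # --- positions: cis proteins sit within 1 Mb of their assigned marker
    cis_prots = prot_ids[: config.n_cis_effects]
    cis_markers = list(
        rng.choice(np.asarray(genotypes.markers, dtype=object),
                   size=config.n_cis_effects, replace=False)
    )
    chrom_len = _chrom_length_bp(config)
    anno_rows = []
    cis_assign: dict = {}
    for pid, mk in zip(cis_prots, cis_markers):
        pos = int(markers.loc[mk, "pos_bp"])
        tss = int(np.clip(pos + rng.integers(-900_000, 900_001), 1, chrom_len))
        gene_len = int(rng.integers(5_000, 50_000))
        anno_rows.append((pid, str(markers.loc[mk, "chrom"]), tss, tss, min(tss + gene_len, chrom_len)))
        cis_assign[pid] = str(mk)
    for pid in prot_ids[config.n_cis_effects:]:
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        tss = int(rng.integers(1, chrom_len + 1))
        gene_len = int(rng.integers(5_000, 50_000))
        anno_rows.append((pid, chrom, tss, tss, min(tss + gene_len, chrom_len)))
    annotation = pd.DataFrame(
        anno_rows, columns=["protein", "chrom", "tss_bp", "exon_start_bp", "exon_end_bp"]
    ).set_index("protein").loc[prot_ids]

    # --- trans effects on proteins without a cis effect, marker on another chromosome
    trans_assign: dict = {}
    trans_beta: dict = {}
    t_size = config.cis_effect_size if config.trans_effect_size is None else config.trans_effect_size
    n_trans = min(config.n_trans_effects, config.n_proteins - config.n_cis_effects)
    trans_prots = prot_ids[config.n_cis_effects: config.n_cis_effects + n_trans]
    for pid in trans_prots:
        own_chrom = annotation.loc[pid, "chrom"]
        other = markers.index[markers["chrom"].astype(str) != str(own_chrom)]
        if len(other) == 0:
            other = markers.index
        mk = str(rng.choice(np.asarray(other, dtype=object)))
        trans_assign[pid] = [mk]
        trans_beta[pid] = [t_size]

    dosage = genotypes.values()
    kin = _kinship_for_sim(np.nan_to_num(dosage, nan=0.5))
    # polygenic draws for all proteins at once: strains x proteins
    jitter = 1e-8 * np.eye(n_strains)
    chol = np.linalg.cholesky(kin + jitter)
    poly = config.polygenic_sd * (chol @ rng.standard_normal((n_strains, config.n_proteins)))

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_proteins)

    # strain-level genetic values
    genetic = poly.T.copy()  # proteins x strains
    marker_pos = {mk: i for i, mk in enumerate(genotypes.markers)}
    cis_beta = {pid: config.cis_effect_size for pid in cis_prots}
    for i, pid in enumerate(prot_ids):
        if pid in cis_assign:
            genetic[i] += cis_beta[pid] * dosage[:, marker_pos[cis_assign[pid]]]
        if pid in trans_assign:
            for mk, b in zip(trans_assign[pid], trans_beta[pid]):
                genetic[i] += b * dosage[:, marker_pos[mk]]

    v_g = genetic.var(axis=1)  # population variance across strains
    if config.residual_sd is not None:
        sigma_e = np.full(config.n_proteins, float(config.residual_sd))
    else:
        h2 = config.polygenic_h2
        if np.any(v_g > 0) and h2 <= 0.5:
            raise ValueError(
                "polygenic_h2 <= 0.5 is unreachable by the strain-mean estimator "
                "with two replicates; set residual_sd explicitly instead"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma_e = np.sqrt(np.where(v_g > 0, v_g * (1.0 - h2) / (h2 - 0.5), 0.0)) if h2 > 0.5 \
                else np.zeros(config.n_proteins)

    tot = v_g + sigma_e ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        true_h2 = pd.Series(
            np.where(tot > 0, (v_g + sigma_e ** 2 / 2.0) / tot, np.nan),
            index=prot_ids, name="true_h2",
        )

    # --- samples: one male + one female per strain, strain blocks per batch
    sample_ids, meta_rows = [], []
    batch_of_strain = {s: i % config.n_batches for i, s in enumerate(strains)}
    for s in strains:
        for sex in ("M", "F"):
            sid = f"{s}_{sex}"
            sample_ids.append(sid)
            meta_rows.append((sid, s, sex, int(batch_of_strain[s])))
    samples = pd.DataFrame(meta_rows, columns=["sample", "strain", "sex", "batch"]).set_index("sample")
    # channel index within batch, in sample order
    samples["channel"] = samples.groupby("batch").cumcount()

    sex_effect = rng.normal(0.0, config.sex_effect_sd, size=config.n_proteins)
    batch_effect = rng.normal(0.0, config.batch_effect_sd, size=(config.n_proteins, config.n_batches))

    strain_idx = {s: i for i, s in enumerate(strains)}
    vals = np.empty((config.n_proteins, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        s = samples.loc[sid, "strain"]
        sex = samples.loc[sid, "sex"]
        b = samples.loc[sid, "batch"]
        sign = 0.5 if sex == "M" else -0.5
        vals[:, j] = (
            baseline
            + genetic[:, strain_idx[s]]
            + sign * sex_effect
            + batch_effect[:, b]
        )
    vals += rng.standard_normal(vals.shape) * sigma_e[:, None]

    matrix = ProteinMatrix(pd.DataFrame(vals, index=prot_ids, columns=sample_ids), samples)
    truth = GroundTruth(
        cis_assignments=cis_assign,
        trans_assignments=trans_assign,
        true_h2=true_h2,
        annotation=annotation,
        cis_beta=cis_beta,
        trans_beta=trans_beta,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# PSM-level TMT data
# ---------------------------------------------------------------------------

def build_impurity_matrix(plex: int, spill: float) -> np.ndarray:
    """Tri-diagonal isotopic-impurity mixing matrix for one plex.

    Column j keeps fraction ``1 - spill`` of its signal and leaks ``spill/2``
    into each adjacent channel (edge channels lose the outward half).  Columns
    therefore sum to at most 1 and the diagonal dominates for spill < 0.5.
    """
    if spill < 0:
        raise ValueError("spill must be >= 0")
    if spill >= 0.5:
        raise ValueError("impurity spill >= 0.5 makes the matrix non-diagonally-dominant")
    m = np.eye(plex) * (1.0 - spill)
    for j in range(plex):
        if j > 0:
            m[j - 1, j] += spill / 2.0
        if j + 1 < plex:
            m[j + 1, j] += spill / 2.0
    return m


def simulate_psms(
    protein_truth: ProteinMatrix, config: SimConfig
) -> tuple[PSMTable, dict]:
    """Expand a protein matrix into PSM-level reporter intensities per batch.

    Each protein yields ``psm_per_protein`` PSMs with a per-PSM abundance
    offset, a per-channel loading effect, multiplicative (log-additive) noise,
    and isotopic-impurity mixing through the batch's plex matrix.
    """
    config.validate()
    rng = config.rng(2)
    samples = protein_truth.samples
    batches = sorted(samples["batch"].unique())
    impurity = {int(b): build_impurity_matrix(int((samples["batch"] == b).sum()), config.impurity_spill)
                for b in batches}

    prot_ids = protein_truth.proteins
    n_psm = config.psm_per_protein
    offsets = rng.normal(0.0, config.psm_offset_sd, size=(len(prot_ids), n_psm))
    channel_eff = {
        int(b): rng.normal(0.0, config.channel_effect_sd, size=int((samples["batch"] == b).sum()))
        for b in batches
    }

    all_cols = list(protein_truth.values.columns)
    rows = []
    intens = np.full((len(prot_ids) * n_psm, len(all_cols)), np.nan)
    col_pos = {c: i for i, c in enumerate(all_cols)}
    r = 0
    for pi, pid in enumerate(prot_ids):
        for k in range(n_psm):
            rows.append((f"{pid}_psm{k + 1}", pid, -1))  # batch filled later (per-batch mixing)
            r += 1

    # per batch: compute true intensities, add noise, mix through impurity matrix
    log2_truth = protein_truth.values.to_numpy()
    for b in batches:
        b = int(b)
        batch_cols = list(samples.index[samples["batch"] == b])
        order = np.argsort(samples.loc[batch_cols, "channel"].to_numpy())
        batch_cols = [batch_cols[i] for i in order]
        cidx = [col_pos[c] for c in batch_cols]
        truth_b = log2_truth[:, [list(protein_truth.values.columns).index(c) for c in batch_cols]]
        eff = channel_eff[b]
        for pi in range(len(prot_ids)):
            for k in range(n_psm):
                log2 = truth_b[pi] + offsets[pi, k] + eff
                if config.psm_noise_sd > 0:
                    log2 = log2 + rng.normal(0.0, config.psm_noise_sd, size=log2.shape)
                raw = np.power(2.0, log2)
                mixed = impurity[b] @ raw
                intens[pi * n_psm + k, cidx] = mixed

    key = pd.DataFrame(rows, columns=["psm_id", "protein_id", "batch"])
    # a PSM is observed in every batch (the same peptide is measured per plex);
    # represent as one row per (psm, batch) to keep batch-wise processing simple
    out_rows = []
    for b in batches:
        b = int(b)
        batch_cols = protein_truth.samples.index[protein_truth.samples["batch"] == b]
        block = key.copy()
        block["batch"] = b
        block["psm_id"] = block["psm_id"] + f"_b{b}"
        wide = pd.DataFrame(np.nan, index=block.index, columns=all_cols)
        wide.loc[:, list(batch_cols)] = intens[:, [col_pos[c] for c in batch_cols]]
        out_rows.append(pd.concat([block, wide], axis=1))
    data = pd.concat(out_rows, ignore_index=True)
    return PSMTable(data, samples.copy()), impurity


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_trait(
    genotypes: GenotypeMatrix,
    protein: ProteinMatrix,
    truth: GroundTruth,
    model: str,
    config: SimConfig,
    anchor_protein: Optional[str] = None,
    effect: float = 1.0,
    noise_frac: float = 0.5,
) -> TraitSim:
    """Generate a strain-level trait under an explicit causal structure.

    causal      : T = a*P + eps           (protein mediates the locus effect)
    reactive    : T = b*Q + eps, then P is regenerated as c*T + eps'
    pleiotropic : T = b*Q + eps, independent of P given Q
    null        : pure noise

    ``noise_frac`` sets the residual sd as a fraction of the signal sd.
    """
    if model not in TRAIT_MODELS:
        raise ValueError(f"unknown trait model {model!r}")
    rng = config.rng(3)
    if anchor_protein is None:
        if not truth.cis_assignments:
            raise ValueError("no cis assignments to anchor the trait on")
        anchor_protein = next(iter(truth.cis_assignments))
    marker = truth.cis_assignments.get(anchor_protein)
    if marker is None:
        raise ValueError(f"{anchor_protein} has no cis marker")

    strains = protein.strains
    q = genotypes.dosage.loc[strains, marker].to_numpy(dtype=float)
    p = protein.strain_means().loc[anchor_protein, strains].to_numpy(dtype=float)

    def noisy(signal: np.ndarray) -> np.ndarray:
        sd = float(np.std(signal))
        sd = sd if sd > 0 else 1.0
        return signal + rng.normal(0.0, noise_frac * sd, size=signal.shape)

    out_protein = protein
    if model == "causal":
        t = noisy(effect * p)
    elif model == "pleiotropic":
        t = noisy(effect * q)
    elif model == "reactive":
        t = noisy(effect * q)
        new_p = noisy(effect * t)
        out_values = protein.values.copy()
        # copy the regenerated strain values onto both sex replicates
        for i, s in enumerate(strains):
            cols = protein.samples.index[protein.samples["strain"] == s]
            out_values.loc[anchor_protein, cols] = new_p[i]
        out_protein = ProteinMatrix(out_values, protein.samples.copy())
    else:  # null
        t = rng.standard_normal(len(strains))

    trait = pd.Series(t, index=strains, name="trait")
    return TraitSim(trait=trait, model=model, anchor_protein=anchor_protein,
                    anchor_marker=marker, protein=out_protein)
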