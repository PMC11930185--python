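"""File formats and run configuration.

Readers/writers for the GeneNetwork-style ``.geno`` genotype dialect and the
TSV artifacts every stage exchanges (protein matrices with a sample-metadata
sidecar, PSM tables, annotation, traits, impurity matrices), plus the flat
key=value run configuration and an append-only run log.

All genomic coordinates are held 1-based inclusive in bp in memory; the
``Mb`` dialect is converted at the reader.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ProteinMatrix, PSMTable
from .sim import SimConfig

__all__ = [
    "read_geno",
    "write_geno",
    "read_protein_matrix",
    "write_protein_matrix",
    "read_psm_table",
    "write_psm_table",
    "read_annotation",
    "write_annotation",
    "read_impurity",
    "write_impurity",
    "RunConfig",
    "RunLog",
]

_ALLELE_TO_DOSE = {"B": 0.0, "D": 1.0, "H": np.nan, "U": np.nan}
_DOSE_TO_ALLELE = {0.0: "B", 1.0: "D"}


def read_geno(path, pos_unit: str | None = None) -> GenotypeMatrix:
    """Parse a GeneNetwork-``.geno``-style TSV.

    Lines starting with ``#`` or ``@`` are comments.  The header row names
    the columns ``Chr``, ``Locus``, ``cM``, then optionally ``bp`` or ``Mb``,
    then one column per strain.  Calls are ``B`` (reference founder, dose 0),
    ``D`` (alternative founder, dose 1); ``H`` and ``U`` become missing.
    ``pos_unit`` overrides the position dialect inferred from the header.
    """
    path = Path(path)
    header = None
    rows = []
    n_missing = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("@"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            rows.append((lineno, parts))
    if header is None or not rows:
        raise ValueError(f"{path}: no genotype records")

    fixed = [c for c in header if c in {"Chr", "Locus", "cM", "bp", "Mb"}]
    strain_cols = header[len(fixed):]
    has_bp = "bp" in fixed
    has_mb = "Mb" in fixed
    unit = pos_unit or ("Mb" if has_mb and not has_bp else "bp")

    ids, chroms, pos_bp, cm, doses = [], [], [], [], []
    seen = set()
    for lineno, parts in rows:
        if len(parts) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
        rec = dict(zip(header, parts))
        locus = rec["Locus"]
        if locus in seen:
            raise ValueError(f"{path}:{lineno}: duplicate marker id {locus!r}")
        seen.add(locus)
        ids.append(locus)
        chroms.append(rec["Chr"])
        cm.append(float(rec.get("cM", "nan")))
        if has_bp or has_mb:
            raw = float(rec["bp"] if has_bp else rec["Mb"])
            pos_bp.append(int(round(raw * 1e6)) if unit == "Mb" else int(round(raw)))
        else:
            pos_bp.append(int(round(float(rec["cM"]) * 1e6)))  # cM-only files: 1 cM ~ 1 Mb stand-in
        calls = []
        for s in strain_cols:
            code = rec[s].strip()
            if code not in _ALLELE_TO_DOSE:
                raise ValueError(f"{path}:{lineno}: unknown allele code {code!r} for strain {s}")
            if code in {"H", "U"}:
                n_missing += 1
            calls.append(_ALLELE_TO_DOSE[code])
        doses.append(calls)

    marker_map = pd.DataFrame({"chrom": chroms, "pos_bp": pos_bp, "cM": cm},
                              index=pd.Index(ids, name="marker"))
    dosage = pd.DataFrame(np.asarray(doses, dtype=float).T, index=strain_cols, columns=marker_map.index)
    g = GenotypeMatrix(dosage, marker_map)
    g.dosage.attrs["n_missing_calls"] = n_missing
    return g


def write_geno(genotypes: GenotypeMatrix, path) -> None:
    """Write the ``.geno`` dialect with bp positions (inverse of read_geno)."""
    path = Path(path)
    strains = genotypes.strains
    with open(path, "w") as fh:
        fh.write("\t".join(["Chr", "Locus", "cM", "bp", *strains]) + "\n")
        for mk, row in genotypes.marker_map.iterrows():
            calls = []
            for s in strains:
                v = genotypes.dosage.loc[s, mk]
                calls.append("U" if pd.isna(v) else _DOSE_TO_ALLELE[float(v)])
            fh.write("\t".join([str(row["chrom"]), str(mk), f"{row['cM']:g}",
                                str(int(row["pos_bp"])), *calls]) + "\n")


def write_protein_matrix(matrix: ProteinMatrix, values_path, samples_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="protein_id")
    matrix.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_protein_matrix(values_path, samples_path) -> ProteinMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="protein_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return ProteinMatrix(values, samples)


def write_psm_table(psms: PSMTable, data_path, samples_path) -> None:
    psms.data.to_csv(data_path, sep="\t", index=False)
    psms.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_psm_table(data_path, samples_path) -> PSMTable:
    data = pd.read_csv(data_path, sep="\t")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return PSMTable(data, samples)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="protein")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein", dtype={"chrom": str})


def write_impurity(matrices: dict, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for batch, m in matrices.items():
        pd.DataFrame(m).to_csv(directory / f"impurity_batch{batch}.csv", index=False)


def read_impurity(directory) -> dict:
    directory = Path(directory)
    out = {}
    for f in sorted(directory.glob("impurity_batch*.csv")):
        batch = int(f.stem.replace("impurity_batch", ""))
        out[batch] = pd.read_csv(f).to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# Run configuration and logging
# ---------------------------------------------------------------------------

_STAGES = ("simulate", "quant", "stats", "map", "coloc", "causal")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with paper-default thresholds."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple = _STAGES
    out_dir: str = "ripqtl_run"
    # quantification
    min_intensity: float = 1000.0
    min_median: float = 5000.0
    trim_fraction: float = 0.1
    # differential expression
    adj_p_cut: float = 0.01
    lfc_cut: float = 1.0
    # mapping
    cis_window_bp: float = 1_000_000
    trans_gap_bp: float = 5_000_000
    n_perm: int = 10
    target_fdr: float = 0.05
    # colocalization
    flank_bp: float = 500_000
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    pp4_cut: float = 0.8
    # causal trait model
    trait_model: str = "causal"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.sim.validate()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` text config (# comments allowed).

        Keys matching SimConfig fields configure the simulator; all other
        keys must match RunConfig fields.  ``stages`` is comma-separated.
        """
        sim_fields = {f.name: f for f in dataclasses.fields(SimConfig)}
        run_fields = {f.name: f for f in dataclasses.fields(cls) if f.name != "sim"}
        sim_kwargs, run_kwargs = {}, {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key in sim_fields:
                    sim_kwargs[key] = _coerce(raw, sim_fields[key].type)
                elif key in run_fields:
                    if key == "stages":
                        run_kwargs[key] = tuple(s.strip() for s in raw.split(",") if s.strip())
                    else:
                        run_kwargs[key] = _coerce(raw, run_fields[key].type)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        seed = run_kwargs.get("seed")
        if seed is not None and "seed" not in sim_kwargs:
            sim_kwargs["seed"] = seed
        return cls(sim=SimConfig(**sim_kwargs), **run_kwargs)


def _coerce(raw: str, annot) -> object:
    s = str(annot)
    if raw.lower() in {"none", "null"}:
        return None
    if "int" in s:
        return int(raw)
    if "float" in s:
        return float(raw)
    if "bool" in s:
        return raw.lower() in {"1", "true", "yes"}
    return raw


@dataclass
class RunLog:
    """Append-only record of what each stage did, with counts and thresholds."""

    entries: list = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.entries.append({"stage": stage, **info})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                stage = e["stage"]
                rest = "\t".join(f"{k}={v}" for k, v in e.items() if k != "stage")
                fh.write(f"{stage}\t{rest}\n")
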