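"""Shared in-memory containers for the pipeline.

All tabular data is carried as pandas DataFrames; the dataclasses below bind
the value tables to their coordinate / metadata tables so stages cannot drift
out of alignment.

Conventions
-----------
* Genotype dosage is founder-allele dose in {0, 1} (fully inbred lines);
  ``NaN`` marks residual heterozygosity or failed calls from real files.
* Genomic coordinates are 1-based inclusive base pairs everywhere in memory;
  file dialect conversions happen in :mod:`ripqtl.io` only.
* Protein abundance is log2 reporter intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "ProteinMatrix", "PSMTable"]


@dataclass
class GenotypeMatrix:
    """Strains x markers founder-allele dosage with a genetic map.

    Parameters
    ----------
    dosage : DataFrame
        Rows are strains, columns are marker ids, values in {0, 1} (float so
        missing calls can be ``NaN``).  0 is the reference founder allele
        (``B`` in GeneNetwork files), 1 the alternative founder (``D``).
    marker_map : DataFrame
        Indexed by marker id with columns ``chrom`` (str), ``pos_bp`` (int)
        and ``cM`` (float), in genome order.
    """

    dosage: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosage.shape[1] != len(self.marker_map):
            raise ValueError("dosage columns and marker_map rows differ")
        if not self.dosage.columns.equals(self.marker_map.index):
            # align rather than fail: readers may deliver either order
            self.dosage = self.dosage[self.marker_map.index]

    @property
    def strains(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def markers(self) -> list[str]:
        return list(self.marker_map.index)

    @property
    def n_strains(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def markers_in_window(self, chrom: str, start_bp: float, end_bp: float) -> list[str]:
        """Marker ids on ``chrom`` with ``start_bp <= pos <= end_bp``."""
        m = self.marker_map
        sel = (m["chrom"].astype(str) == str(chrom)) & (m["pos_bp"] >= start_bp) & (m["pos_bp"] <= end_bp)
        return list(m.index[sel])

    def values(self) -> np.ndarray:
        return self.dosage.to_numpy(dtype=float)


@dataclass
class ProteinMatrix:
    """Proteins x samples log2 abundance with sample metadata.

    ``samples`` is indexed by sample id and carries ``strain``, ``sex``
    (``"M"``/``"F"``), ``batch`` and ``channel`` columns.  Missing abundances
    are explicit ``NaN``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples metadata missing for: {missing[:5]}")
        self.samples = self.samples.loc[list(self.values.columns)]

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def strains(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples["strain"]:
            seen.setdefault(s, None)
        return list(seen)

    def strain_means(self) -> pd.DataFrame:
        """Per-strain mean abundance (proteins x strains, strain order preserved)."""
        groups = self.samples.groupby("strain", sort=False).groups
        cols = {strain: self.values[list(ids)].mean(axis=1) for strain, ids in groups.items()}
        return pd.DataFrame(cols, index=self.values.index)

    def subset_sex(self, sex: str) -> "ProteinMatrix":
        if sex not in {"M", "F"}:
            raise ValueError(f"unknown sex {sex!r}")
        keep = self.samples.index[self.samples["sex"] == sex]
        if len(keep) == 0:
            raise ValueError(f"no samples of sex {sex!r}")
        return ProteinMatrix(self.values[list(keep)].copy(), self.samples.loc[keep].copy())


@dataclass
class PSMTable:
    """PSM-level reporter intensities in wide layout.

    ``data`` has key columns ``psm_id``, ``protein_id``, ``batch`` followed by
    one intensity column per sample; intensities for samples outside the PSM's
    batch are ``NaN``.  ``samples`` is the same metadata table as on
    :class:`ProteinMatrix` (sample -> strain/sex/batch/channel).
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    key_columns: tuple[str, ...] = field(default=("psm_id", "protein_id", "batch"), repr=False)

    def __post_init__(self) -> None:
        for col in self.key_columns:
            if col not in self.data.columns:
                raise ValueError(f"PSM table lacks required column {col!r}")

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.key_columns]

    @property
    def batches(self) -> list:
        seen: dict = {}
        for b in self.data["batch"]:
            seen.setdefault(b, None)
        return list(seen)

    def batch_samples(self, batch) -> list[str]:
        """Sample ids measured in ``batch``, in channel order."""
        sub = self.samples[self.samples["batch"] == batch]
        if "channel" in sub.columns:
            sub = sub.sort_values("channel")
        return list(sub.index)

    def batch_rows(self, batch) -> pd.DataFrame:
        return self.data[self.data["batch"] == batch]

    def copy(self) -> "PSMTable":
        return PSMTable(self.data.copy(), self.samples.copy())
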