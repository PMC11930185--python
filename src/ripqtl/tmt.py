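"""TMT reporter-ion quantification: PSM table -> log2 protein x sample matrix.

The pipeline order is fixed: impurity correction -> intensity filtering ->
trimmed-median channel normalization -> protein rollup (per batch) -> batch
merging.  Each step logs how many records it kept and dropped.

Rollup follows the mean-centered averaging scheme used by TMT pipelines:
per-PSM log2 intensities are centered on their cross-sample mean, centered
profiles are averaged over a protein's PSMs, and the absolute level is
restored from the grand mean of the protein's three most abundant PSMs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import PSMTable, ProteinMatrix

__all__ = [
    "correct_impurities",
    "filter_psms",
    "normalize_trimmed_median",
    "rollup_proteins",
    "merge_batches",
    "quantify",
    "trimmed_location",
]

log = logging.getLogger(__name__)


def _batch_matrix(impurity, batch, plex: int) -> np.ndarray:
    """Resolve the impurity matrix for a batch from a dict keyed by batch or plex."""
    if isinstance(impurity, np.ndarray):
        m = impurity
    elif batch in impurity:
        m = impurity[batch]
    elif plex in impurity:
        m = impurity[plex]
    else:
        raise KeyError(f"no impurity matrix for batch {batch!r} (plex {plex})")
    m = np.asarray(m, dtype=float)
    if m.shape != (plex, plex):
        raise ValueError(f"impurity matrix for batch {batch!r} is {m.shape}, expected {(plex, plex)}")
    return m


def correct_impurities(psms: PSMTable, impurity) -> PSMTable:
    """Undo isotopic-impurity mixing by solving M x = observed per PSM.

    ``impurity`` is a single matrix or a dict keyed by batch id (or plex
    size).  Negative components of the exact solution are clipped to zero.
    """
    out = psms.copy()
    for batch in out.batches:
        cols = out.batch_samples(batch)
        m = _batch_matrix(impurity, batch, len(cols))
        if np.linalg.cond(m) > 1e12:
            raise np.linalg.LinAlgError(f"impurity matrix for batch {batch!r} is singular")
        rows = out.data["batch"] == batch
        obs = out.data.loc[rows, cols].to_numpy(dtype=float)
        x = np.linalg.solve(m, obs.T).T
        out.data.loc[rows, cols] = np.clip(x, 0.0, None)
    return out


def filter_psms(psms: PSMTable, min_intensity: float = 1000.0,
                min_median: float = 5000.0) -> PSMTable:
    """Discard low-intensity PSMs.

    A PSM survives if, across its batch's channels, both the minimum
    intensity is >= ``min_intensity`` and the median is >= ``min_median``.
    """
    if min_intensity < 0 or min_median < 0:
        raise ValueError("thresholds must be >= 0")
    keep = np.zeros(len(psms.data), dtype=bool)
    for batch in psms.batches:
        cols = psms.batch_samples(batch)
        rows = (psms.data["batch"] == batch).to_numpy()
        block = psms.data.loc[rows, cols].to_numpy(dtype=float)
        mins = np.nanmin(block, axis=1)
        meds = np.nanmedian(block, axis=1)
        keep[rows] = (mins >= min_intensity) & (meds >= min_median)
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_psms removed %d of %d PSMs", dropped, len(keep))
    return PSMTable(psms.data.loc[keep].reset_index(drop=True), psms.samples.copy())


def trimmed_location(values: np.ndarray, trim: float = 0.1) -> float:
    """Robust location: mean of the central ``1 - 2*trim`` of sorted values.

    With trim = 0 this is the plain mean; NaNs are ignored.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    k = int(np.floor(trim * v.size))
    core = v[k: v.size - k] if v.size - 2 * k > 0 else v
    return float(core.mean())


def normalize_trimmed_median(psms: PSMTable, trim_fraction: float = 0.1) -> PSMTable:
    """Equalize channel loadings within each batch.

    Each channel's log2 intensities are shifted by a constant so that its
    trimmed location matches the cross-channel mean of trimmed locations;
    on the intensity scale this is a per-channel multiplicative factor.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    out = psms.copy()
    for batch in out.batches:
        cols = out.batch_samples(batch)
        rows = out.data["batch"] == batch
        block = out.data.loc[rows, cols].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            logs = np.log2(np.where(block > 0, block, np.nan))
        if np.all(np.isnan(logs)):
            raise ValueError(f"batch {batch!r}: all channels missing")
        tms = []
        for j, c in enumerate(cols):
            col = logs[:, j]
            if not np.isfinite(col).any():
                raise ValueError(f"batch {batch!r}: channel {c!r} has no finite intensities")
            tms.append(trimmed_location(col, trim_fraction))
        tms = np.asarray(tms)
        offsets = tms.mean() - tms  # log2 shift per channel
        out.data.loc[rows, cols] = block * np.power(2.0, offsets)[None, :]
    return out


def rollup_proteins(psms: PSMTable, top_n: int = 3) -> ProteinMatrix:
    """Summarise PSMs to one log2 profile per protein, batch by batch.

    Within a batch: per-PSM log2 values are mean-centered across samples,
    averaged over the protein's PSMs, and re-anchored at the grand mean log2
    intensity of the protein's ``top_n`` most abundant PSMs (all PSMs when
    fewer).  Batches are then merged with :func:`merge_batches`.
    """
    per_batch: list[ProteinMatrix] = []
    for batch in psms.batches:
        cols = psms.batch_samples(batch)
        block = psms.batch_rows(batch)
        with np.errstate(divide="ignore"):
            logs = np.log2(block[cols].to_numpy(dtype=float))
        logs[~np.isfinite(logs)] = np.nan
        centered = logs - np.nanmean(logs, axis=1, keepdims=True)
        psm_mean = np.nanmean(logs, axis=1)

        frame = pd.DataFrame(centered, columns=cols)
        frame.insert(0, "protein_id", block["protein_id"].to_numpy())
        frame["_psm_mean"] = psm_mean

        profiles, skipped = {}, 0
        for pid, grp in frame.groupby("protein_id", sort=False):
            sub = grp[cols].to_numpy()
            if not np.isfinite(sub).any():
                skipped += 1
                continue
            rel = np.nanmean(sub, axis=0)
            means = np.sort(grp["_psm_mean"].to_numpy())[::-1]
            absolute = float(np.nanmean(means[:top_n]))
            profiles[pid] = rel + absolute
        if skipped:
            log.info("rollup: batch %r dropped %d proteins with no surviving PSMs", batch, skipped)
        values = pd.DataFrame(profiles, index=cols).T
        meta = psms.samples.loc[cols]
        per_batch.append(ProteinMatrix(values, meta))
    return merge_batches(per_batch)


def merge_batches(parts: list[ProteinMatrix]) -> ProteinMatrix:
    """Combine per-batch protein matrices into one matrix.

    Per protein and batch the profile is mean-centered (a plain stand-in for
    heavier batch-effect removal) and the absolute level is restored as the
    mean of the per-batch levels.  Proteins absent from some batches are kept
    and flagged in ``samples.attrs['partially_observed']``.
    """
    if not parts:
        raise ValueError("nothing to merge")
    if len(parts) == 1:
        return parts[0]
    all_prot: dict[str, None] = {}
    for p in parts:
        for pid in p.proteins:
            all_prot.setdefault(pid, None)
    prot_ids = list(all_prot)

    blocks, levels = [], []
    for p in parts:
        v = p.values.reindex(prot_ids)
        level = v.mean(axis=1)
        blocks.append(v.sub(level, axis=0))
        levels.append(level)
    level = pd.concat(levels, axis=1).mean(axis=1)
    merged = pd.concat(blocks, axis=1).add(level, axis=0)
    samples = pd.concat([p.samples for p in parts])
    merged = merged[list(samples.index)]

    n_batches = len(parts)
    seen = pd.concat([p.values.reindex(prot_ids).notna().any(axis=1) for p in parts], axis=1)
    partial = list(seen.index[seen.sum(axis=1) < n_batches])
    out = ProteinMatrix(merged, samples)
    out.samples.attrs["partially_observed"] = partial
    if partial:
        log.info("merge_batches: %d proteins not observed in every batch", len(partial))
    return out


def quantify(psms: PSMTable, impurity, min_intensity: float = 1000.0,
             min_median: float = 5000.0, trim_fraction: float = 0.1) -> ProteinMatrix:
    """Full quantification chain: correct -> filter -> normalize -> rollup."""
    corrected = correct_impurities(psms, impurity)
    kept = filter_psms(corrected, min_intensity=min_intensity, min_median=min_median)
    normed = normalize_trimmed_median(kept, trim_fraction=trim_fraction)
    return rollup_proteins(normed)
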