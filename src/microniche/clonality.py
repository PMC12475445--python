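"""Post-count barcode clonality analysis.

Depth normalization (rounded half-up), the 1000-count low-count filter,
index-hopping bleed-through removal, and clone-composition summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BarcodeCountTable

__all__ = [
    "preprocess_counts",
    "filter_index_hopping",
    "clone_summary",
    "CloneSummary",
]

#: Monoclonality call threshold on the top-clone frequency.
MONOCLONAL_THRESHOLD = 0.99


def preprocess_counts(
    table: BarcodeCountTable,
    min_count: int = 1000,
    reference_depth="mean",
) -> tuple[BarcodeCountTable, pd.Series]:
    """Normalize each sample to a reference depth, then drop low counts.

    Each sample is scaled by ``reference_depth / sample_total`` and rounded
    half-up to integers; counts below ``min_count`` are then set to 0 and
    barcodes left with all-zero rows are dropped.  Scaling is monotone, so
    within-sample barcode ranking is preserved.

    Returns the filtered table and the per-sample removed mass (zeroed
    normalized reads as a fraction of the sample's normalized total).
    """
    totals = table.sample_totals.astype(float)
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(table.samples, zero) if z]
        raise ValueError(f"sample(s) with zero total count: {bad}")
    if reference_depth == "mean":
        ref = totals.mean()
    else:
        ref = float(reference_depth)
        if not ref > 0:
            raise ValueError("reference_depth must be positive")
    scaled = table.counts * (ref / totals)[None, :]
    normalized = np.floor(scaled + 0.5).astype(np.int64)  # round half-up
    filtered = np.where(normalized < min_count, 0, normalized)
    norm_totals = normalized.sum(axis=0).astype(float)
    removed = (normalized - filtered).sum(axis=0) / np.where(norm_totals > 0, norm_totals, 1.0)
    removed_mass = pd.Series(removed, index=table.samples, name="removed_mass")
    keep = filtered.sum(axis=1) > 0
    out = BarcodeCountTable(
        barcodes=[b for b, k in zip(table.barcodes, keep) if k],
        samples=list(table.samples),
        counts=filtered[keep],
    )
    return out, removed_mass


def filter_index_hopping(table: BarcodeCountTable, hop_fraction: float = 0.05) -> BarcodeCountTable:
    """Remove index-hopping bleed-through counts.

    For each barcode, counts below ``hop_fraction`` times the barcode's
    maximum count over samples are set to 0.  The maximal sample's count is
    never removed, and the filter is idempotent.
    """
    if not (0 <= hop_fraction < 1):
        raise ValueError("hop_fraction must be in [0, 1)")
    counts = table.counts.copy()
    row_max = counts.max(axis=1, keepdims=True)
    counts[counts < hop_fraction * row_max] = 0
    return BarcodeCountTable(list(table.barcodes), list(table.samples), counts)


@dataclass
class CloneSummary:
    """Per-sample clone composition plus cross-sample uniqueness."""

    per_sample: pd.DataFrame
    frequencies: dict  # sample -> DataFrame(barcode, frequency) descending
    n_barcodes: int
    single_sample_fraction: float


def clone_summary(
    table: BarcodeCountTable,
    frequency_floor: float = 0.001,
    monoclonal_threshold: float = MONOCLONAL_THRESHOLD,
) -> CloneSummary:
    """Clone frequencies, top-clone fractions and single-sample uniqueness.

    Per-sample clone frequencies are counts over the sample total; a sample
    is flagged monoclonal when its top clone holds at least
    ``monoclonal_threshold`` of the reads.  The uniqueness fraction is the
    share of retained barcodes detected in exactly one sample.
    """
    if len(table.barcodes) == 0 or table.counts.sum() == 0:
        raise ValueError("empty count table")
    per_rows = []
    frequencies = {}
    for j, sample in enumerate(table.samples):
        col = table.counts[:, j]
        total = col.sum()
        if total == 0:
            per_rows.append(
                {
                    "sample": sample,
                    "total": 0,
                    "top_clone_fraction": np.nan,
                    "n_clones_above_floor": 0,
                    "monoclonal": False,
                }
            )
            frequencies[sample] = pd.DataFrame(columns=["barcode", "frequency"])
            continue
        freq = col / total
        order = np.argsort(-freq, kind="stable")
        nz = order[freq[order] > 0]
        frequencies[sample] = pd.DataFrame(
            {"barcode": [table.barcodes[i] for i in nz], "frequency": freq[nz]}
        )
        top = float(freq[nz[0]])
        per_rows.append(
            {
                "sample": sample,
                "total": int(total),
                "top_clone_fraction": top,
                "n_clones_above_floor": int((freq >= frequency_floor).sum()),
                "monoclonal": bool(top >= monoclonal_threshold),
            }
        )
    present_in = (table.counts > 0).sum(axis=1)
    detected = present_in > 0
    single = float((present_in[detected] == 1).sum()) / detected.sum()
    return CloneSummary(
        per_sample=pd.DataFrame(per_rows),
        frequencies=frequencies,
        n_barcodes=int(detected.sum()),
        single_sample_fraction=single,
    )
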