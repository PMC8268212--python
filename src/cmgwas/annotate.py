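"""Nearest-gene annotation and pleiotropy profiles for selected variants."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GeneSet

GENE_WINDOW = 100_000     # bp either side, boundary inclusive
T_REPORT_DEFAULT = 1.96   # |t| reporting threshold (2.0 also conventional)


@dataclass
class GeneAnnotation:
    """A gene within the annotation window of a variant.

    ``distance`` is 0 when the variant lies inside the gene interval,
    otherwise the gap to the nearer interval end. ``side`` is relative to
    gene coordinates (strand is ignored throughout).
    """

    variant_key: str
    gene: str
    distance: int
    side: str   # within | upstream | downstream

    def label(self) -> str:
        return f"{self.gene}^{self.distance / 1000:g}"


def nearest_genes(chrom: str, pos: int, genes: GeneSet,
                  window: int = GENE_WINDOW,
                  variant_key: str = "") -> list[GeneAnnotation]:
    """All genes whose interval lies within ``window`` bp of the position
    (boundary inclusive: a gene ending exactly ``window`` away is reported),
    sorted by distance then name."""
    t = genes.table
    sub = t[t["chrom"].astype(str) == str(chrom)]
    out: list[GeneAnnotation] = []
    for start, end, name in zip(sub["start"], sub["end"], sub["name"]):
        if start <= pos <= end:
            dist, side = 0, "within"
        elif pos < start:
            dist, side = int(start - pos), "upstream"
        else:
            dist, side = int(pos - end), "downstream"
        if dist <= window:
            out.append(GeneAnnotation(variant_key, str(name), dist, side))
    out.sort(key=lambda g: (g.distance, g.gene))
    return out


@dataclass
class PleiotropyProfile:
    """Per-trait signed t-values, masked below the reporting threshold."""

    trait_names: list[str]
    t: np.ndarray
    threshold: float

    @property
    def significant_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.abs(np.nan_to_num(self.t, nan=0.0)) >= self.threshold

    @property
    def n_significant(self) -> int:
        return int(self.significant_mask.sum())

    def masked(self) -> list[float | None]:
        """Reported entries (None where |t| is below the threshold)."""
        return [float(v) if keep else None
                for v, keep in zip(self.t, self.significant_mask)]


def pleiotropy_profile(t_values: np.ndarray, trait_names: list[str],
                       threshold: float = T_REPORT_DEFAULT) -> PleiotropyProfile:
    """Mask a signed-t vector at the reporting threshold (|t| ≥ threshold
    survives; nan entries never do)."""
    t = np.asarray(t_values, dtype=float)
    if t.shape != (len(trait_names),):
        raise ValueError("t vector length does not match trait names")
    return PleiotropyProfile(list(trait_names), t, float(threshold))
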