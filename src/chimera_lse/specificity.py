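"""Chromatogram-based %L1 specificity, normalized to tissue composition.

Sanger traces of RT-PCR products from the chimera show both parental
alleles at polymorphic bases; the relative peak heights estimate the
fraction of transcripts carrying each allele.  Because only ~20% of the
sampled tissue is L1 (penn), a uniformly expressed gene shows a penn
fraction near 0.2, not 0.5.  The %L1 specificity therefore rescales the
observed penn cDNA fraction f by the L1 tissue fraction p (itself estimated
from genomic DNA traces) as a tissue-normalized odds share:

    %L1 = 100 * (f/p) / (f/p + (1-f)/(1-p))

which maps f = p to 50 (uniform expression), f = 1 to 100 (pure L1) and
f = 0 to 0 (no L1 expression).  This functional form is this package's
reconstruction of the published normalization, chosen for those fixed
points; it is isolated in :func:`normalize_l1_specificity` so an
alternative can be swapped in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ChromatogramSite:
    """Peak heights of the two parental bases at one polymorphic site.

    ``height_other`` is the tallest peak of any third base, used to guard
    against miscalls; sites where it exceeds 20% of the total are dropped.
    """

    site_id: str
    height_lyc: float
    height_penn: float
    quality: float | None = None
    material: str = "cDNA"
    height_other: float = 0.0

    def __post_init__(self) -> None:
        if self.height_lyc < 0 or self.height_penn < 0 or self.height_other < 0:
            raise ValueError("peak heights must be non-negative")
        if self.material not in ("cDNA", "gDNA"):
            raise ValueError(f"material must be cDNA or gDNA, got {self.material!r}")


@dataclass
class TissueFraction:
    """Estimated fraction of the sample that is L1 tissue."""

    p: float
    se: float
    n_sites: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("tissue fraction must lie in [0, 1]")


THIRD_PEAK_MAX_FRACTION = 0.2


def site_usable(site: ChromatogramSite) -> bool:
    total = site.height_lyc + site.height_penn
    if total <= 0:
        return False
    if site.height_other > THIRD_PEAK_MAX_FRACTION * (total + site.height_other):
        return False
    return True


def allele_fraction_from_peaks(site: ChromatogramSite) -> float | None:
    """penn fraction f = penn / (penn + lyc); ``None`` for unusable sites."""
    if not site_usable(site):
        logger.info("dropping unusable chromatogram site %s", site.site_id)
        return None
    return site.height_penn / (site.height_penn + site.height_lyc)


def _usable_fractions(sites: Iterable[ChromatogramSite]) -> list[float]:
    fractions = []
    for s in sites:
        f = allele_fraction_from_peaks(s)
        if f is not None:
            fractions.append(f)
    return fractions


def estimate_l1_tissue_fraction(
    gdna_sites: Iterable[ChromatogramSite],
) -> TissueFraction:
    """Estimate the L1 tissue fraction from genomic-DNA peak fractions.

    Both alleles are present in gDNA in proportion to the tissue they come
    from, so the mean per-site penn fraction estimates the L1 share.
    """
    fractions = _usable_fractions(gdna_sites)
    if not fractions:
        raise ValueError("no usable gDNA sites to estimate the tissue fraction")
    arr = np.asarray(fractions)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return TissueFraction(p=float(arr.mean()), se=se, n_sites=len(arr))


def normalize_l1_specificity(f: float, p: float) -> float:
    """Tissue-normalized %L1 specificity (see module docstring)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("cDNA penn fraction must lie in [0, 1]")
    if not 0.0 < p < 1.0:
        raise ValueError("degenerate tissue composition: p must lie strictly in (0, 1)")
    odds_l1 = f / p
    odds_l23 = (1.0 - f) / (1.0 - p)
    return 100.0 * odds_l1 / (odds_l1 + odds_l23)


def summarize_gene_specificity(
    cdna_sites: Sequence[ChromatogramSite],
    p: TissueFraction | float,
    quality_weighted: bool = False,
) -> tuple[float, float, int]:
    """Mean and SE of per-site %L1 for one gene.

    Per-site penn fractions are converted to %L1 individually and then
    averaged (optionally quality-weighted); the SE is taken across whatever
    site/replicate rows are supplied.  With a single site the SE is
    undefined and reported as NaN.
    """
    p_val = p.p if isinstance(p, TissueFraction) else float(p)
    values, weights = [], []
    for s in cdna_sites:
        f = allele_fraction_from_peaks(s)
        if f is None:
            continue
        values.append(normalize_l1_specificity(f, p_val))
        weights.append(s.quality if (quality_weighted and s.quality) else 1.0)
    if not values:
        raise ValueError("no usable cDNA sites for this gene")
    arr = np.asarray(values)
    w = np.asarray(weights)
    mean = float(np.average(arr, weights=w))
    if len(arr) > 1:
        se = float(arr.std(ddof=1) / math.sqrt(len(arr)))
    else:
        se = float("nan")
    return mean, se, len(arr)
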