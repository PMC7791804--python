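"""Region evaluation: RMS contrast of labeled regions and the comparison report.

RMS contrast is the sample standard deviation (divisor N-1) of the pixels of
a region on a [0, 1]-normalized map.  A large background region and a
pulsatile region are compared per feature map; for most dynamic features the
pulsatile region shows the higher contrast, while the behaviour inverts for
the max-frequency map (the pulse frequency is near-constant over the
subject, the background argmax is uniform noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_IDS, FeatureMap
from .postprocess import apply_db_policy, normalize_map

__all__ = ["RegionSpec", "rms_contrast", "contrast_report"]


@dataclass
class RegionSpec:
    """A labeled pixel region (boolean mask) for contrast/similarity evaluation."""

    mask: np.ndarray
    label: str = "BG"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("region mask must be 2-D")
        if self.label not in ("BG", "PULSE"):
            raise ValueError("label must be 'BG' or 'PULSE'")

    @property
    def n_pix(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_rect(
        cls, shape: tuple[int, int], row0: int, row1: int, col0: int, col1: int, label: str = "BG"
    ) -> "RegionSpec":
        """Rectangle [row0, row1) x [col0, col1) on a map of the given shape."""
        mask = np.zeros(shape, dtype=bool)
        mask[row0:row1, col0:col1] = True
        return cls(mask=mask, label=label)


def rms_contrast(fmap: FeatureMap | np.ndarray, region: RegionSpec) -> float:
    """Sample standard deviation of the region's pixels on a normalized map."""
    values = fmap.values if isinstance(fmap, FeatureMap) else np.asarray(fmap)
    if region.mask.shape != values.shape:
        raise ValueError("region mask must match the map shape")
    pix = values[region.mask]
    if pix.size < 2:
        raise ValueError("contrast needs at least 2 region pixels")
    return float(np.std(pix, ddof=1))


def contrast_report(
    bank: dict[str, FeatureMap],
    bg: RegionSpec,
    pulse: RegionSpec,
    apply_db: bool = True,
) -> pd.DataFrame:
    """Per-feature RMS contrasts for the PULSE and BG regions.

    Maps are (optionally) dB-converted per the standard policy, then min-max
    normalized to [0, 1] before the contrast is computed, so features with
    different native ranges are comparable.  Rows follow the bank
    enumeration; rows where PULSE < BG are flagged.
    """
    maps = apply_db_policy(bank) if apply_db else bank
    rows = []
    for fid in FEATURE_IDS:
        if fid not in maps:
            raise ValueError(f"bank is missing feature {fid!r}")
        norm = normalize_map(maps[fid])
        c_pulse = rms_contrast(norm, pulse)
        c_bg = rms_contrast(norm, bg)
        rows.append(
            {
                "feature_id": fid,
                "c_pulse": c_pulse,
                "c_bg": c_bg,
                "pulse_lt_bg": c_pulse < c_bg,
            }
        )
    return pd.DataFrame(rows)
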