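"""Convenience composition of the tiling-array steps.

``build_relative_profile`` runs the full probe-to-profile chain: QC (drop
zero-gDNA probes), pseudogene masking, relative-intensity normalisation,
and window smoothing, with probe genomic coordinates converted to
TSS-oriented positions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .intervals import GenomeInterval
from .tiling import (
    RelativeIntensityProfile,
    TilingProbe,
    apply_masks,
    drop_zero_gdna,
    relative_intensity,
    smooth_profile,
)


def build_relative_profile(
    probes: Sequence[TilingProbe],
    tss_genomic_pos: int = 0,
    masks: Sequence[GenomeInterval] = (),
    tiles_per_window: int = 9,
    windows_per_point: int = 20,
    c: float = 5.0,
    eps: float = 1e-4,
) -> RelativeIntensityProfile:
    """Probe table -> smoothed relative-intensity profile.

    Oriented positions are probe starts minus ``tss_genomic_pos`` (the
    designated TSS), i.e. bp downstream of the TSS for a plus-oriented
    transcript.
    """
    probes = drop_zero_gdna(list(probes))
    if masks:
        probes = apply_masks(probes, masks)
    probes = sorted(probes, key=lambda p: p.interval.start)
    values = relative_intensity(probes, c=c, eps=eps)
    positions = np.array([p.interval.start - tss_genomic_pos for p in probes],
                         dtype=float)
    return smooth_profile(positions, values, tiles_per_window, windows_per_point)
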