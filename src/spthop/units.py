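"""Unit conventions shared across the package.

Positions are nanometres, times are seconds, diffusion coefficients are
um^2/s.  Every conversion between the nm^2/s scale of raw MSD slopes and
the um^2/s scale of reported diffusion coefficients goes through the single
constant below.
"""

NM2_PER_UM2: float = 1.0e6
"""nm^2 per um^2 — divide an nm^2/s slope by this to get um^2/s."""


def d_um2s_to_nm2s(d: float) -> float:
    """Convert a diffusion coefficient from um^2/s to nm^2/s."""
    return d * NM2_PER_UM2


def d_nm2s_to_um2s(d: float) -> float:
    """Convert a diffusion coefficient from nm^2/s to um^2/s."""
    return d / NM2_PER_UM2
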