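"""Default parameter registry: fluorophore and camera constants.

Every value can be overridden through the dataclasses it feeds; nothing in
the analysis code hard-codes these numbers.
"""
from .photophysics import DetectionChain, FluorophoreParams, MortensenParams

# Cy3 in an air-equilibrated aqueous specimen: the triplet lifetime is set
# by O2 collisions (~1e6/s), the singlet lifetime ~1 ns.
CY3 = FluorophoreParams(phi=0.15, phi_t=0.003, tau_s=1e-9, tau_t=1e-6)

FLUOROPHORES = {"cy3": CY3}

#: photocathode quantum efficiency at 570 nm
QE_PHOTOCATHODE = 0.40
#: fraction of emitted photons reaching the photocathode (objective + optics)
COLLECTION_EFF_RANGE = (0.05, 0.10)

DEFAULT_CHAIN = DetectionChain(
    collection_eff_lo=COLLECTION_EFF_RANGE[0],
    collection_eff_hi=COLLECTION_EFF_RANGE[1],
    qe=QE_PHOTOCATHODE,
    frame_time=1e-4,
)

#: CMOS readout noise, rms electrons/pixel/frame
READOUT_NOISE_E = 37.0
#: overall electron amplification after photon detection
OVERALL_GAIN = 8100.0
#: CMOS full well, electrons
FULL_WELL_E = 30000.0
#: photons per camera count at 10-bit depth and 8100x gain
GAIN_CONVERSION_10BIT = 0.00363
#: sample-plane pixel size, nm
PIXEL_NM = 55.1
#: Gaussian PSF standard deviation for Cy3 on the sample plane, nm
PSF_SD_NM = 123.0
#: PSF standard deviation in pixel units
PSF_SD_PX = PSF_SD_NM / PIXEL_NM
#: background photon-count SD per pixel per 0.1-ms frame
BACKGROUND_SD = {"oblique": 0.058, "tir": 0.059}
#: excess noise factor range of the image intensifier
EXCESS_NOISE_F_RANGE = (1.2, 1.4)

#: Mortensen inputs for Cy3 at 10 kHz under saturating TIR illumination
MORTENSEN_CY3_TIR_100 = MortensenParams(
    n_photons=100.0, s_nm=PSF_SD_NM, a_nm=PIXEL_NM, b=BACKGROUND_SD["tir"], f=1.2
)
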