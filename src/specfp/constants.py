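"""Physical constants and package-wide defaults.

All masses are monoisotopic and in daltons (Da).
"""

#: Mass of the proton, Da. Used for [M+H]+ / [M-H]- adduct arithmetic.
PROTON_MASS = 1.007276466

#: Default mass standard deviation (Da) for the Gaussian peak model on
#: high-resolution instruments (Orbitrap/QTOF class).
DEFAULT_SIGMA_MASS_HIGHRES = 0.01

#: Default mass standard deviation (Da) for nominal-mass (unit resolution)
#: instruments such as quadrupole ion traps in low-resolution mode.
DEFAULT_SIGMA_MASS_NOMINAL = 0.5

#: Default intensity standard deviation, in relative units after the
#: spectrum intensities have been normalised to sum to one.
DEFAULT_SIGMA_INTENSITY = 0.05

#: Floors for data-driven peak-variance estimation: replicate spectra with
#: no measurable jitter would otherwise yield a degenerate (zero-width)
#: peak model.
MIN_SIGMA_MASS = 1e-4
MIN_SIGMA_INTENSITY = 1e-3

#: Reliability scores are clipped into [EPS_RELIABILITY, 1 - EPS_RELIABILITY]
#: before Poisson-binomial scoring so that a perfectly (un)reliable bit
#: cannot produce an infinite log score.
EPS_RELIABILITY = 1e-6

#: Soft-margin cost grid used for per-bit model selection: 2^-5 ... 2^10.
DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 11))
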