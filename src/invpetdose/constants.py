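"""Physical constants used across the pipeline.

All rates are per hour, all lengths in mm, all attenuation
coefficients in 1/mm at 511 keV.
"""

import numpy as np

#: Cu-64 physical half-life in hours (standard nuclide datum).
CU64_HALF_LIFE_H: float = 12.7

#: Cu-64 physical decay constant, 1/h.
CU64_LAMBDA_PER_H: float = float(np.log(2.0) / CU64_HALF_LIFE_H)

#: Linear attenuation coefficient of water at 511 keV, 1/mm.
MU_WATER_511_PER_MM: float = 0.0096

#: Linear attenuation coefficient of air at 511 keV, 1/mm (negligible).
MU_AIR_511_PER_MM: float = 0.0

#: Acrylic phantom shell, slightly denser than water.
MU_WALL_511_PER_MM: float = 0.0101

#: FWHM of a Gaussian = FWHM_TO_SIGMA * sigma.
FWHM_TO_SIGMA: float = float(2.0 * np.sqrt(2.0 * np.log(2.0)))
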