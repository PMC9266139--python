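"""Physical constants shared across the package."""

#: 1 clo expressed as a dry thermal resistance, m2K/W
CLO = 0.155

#: Stefan-Boltzmann constant, W/m2K4
SIGMA = 5.670374419e-8

#: volumetric heat capacity of blood per unit flow: W/K per (L/h)
BLOOD_W_PER_K_L_H = 1.067

#: latent heat of evaporation of sweat at skin temperature, J/g
LAMBDA_SWEAT = 2418.0

#: density used to convert sweat mass to volume, g/mL
SWEAT_DENSITY = 1.0

#: metabolic heat equivalent of one met, W/m2 (seated-rest reference)
MET_W_PER_M2 = 58.2

KELVIN = 273.15


def saturation_vapor_pressure_kpa(t_c):
    """Saturation water-vapour pressure over liquid water, kPa.

    Tetens-type (Magnus) formula, accurate to ~0.1% between 0 and 50 degC,
    which covers every physiological and environmental temperature the
    model sees.
    """
    import numpy as np

    t = np.asarray(t_c, dtype=float)
    return 0.61078 * np.exp(17.27 * t / (t + 237.3))
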