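"""Static NIR band assignments used to annotate loadings and VIP reports.

Overtone/combination assignments for the wavelengths that drive meat
spectra in the 908-1676 nm window; shipped as data for report annotation
only — no chemical inference is performed.
"""

import pandas as pd

BAND_ASSIGNMENTS = pd.DataFrame(
    [
        (970, "O-H stretch 2nd overtone", "water / moisture"),
        (1031, "N-H stretch 2nd overtone", "protein"),
        (1143, "C-H stretch 2nd overtone (aromatic)", "tenderness-related"),
        (1193, "C-H stretch 2nd overtone", "fat"),
        (1428, "N-H 1st overtone + O-H 1st overtone", "protein + moisture"),
    ],
    columns=["wavelength_nm", "vibration", "constituent"],
)


def nearest_assignment(wavelength_nm: float, max_distance_nm: float = 30.0):
    """The closest annotated band within ``max_distance_nm``, or None."""
    d = (BAND_ASSIGNMENTS["wavelength_nm"] - wavelength_nm).abs()
    i = d.idxmin()
    if d[i] > max_distance_nm:
        return None
    return BAND_ASSIGNMENTS.loc[i]
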