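"""Published reference values used as inputs and cross-checks.

These constants transcribe summary results reported for the two field surveys
and the chronic-irradiation yeast chemostat experiment that motivate this
package: the AICc ranking of the twenty growth laws, the detection counts of
the one fungal species whose prevalence differed significantly between
exposure groups, and the reported best-fit coefficients (with 95% CIs) of the
best-supported law M1.
"""

from __future__ import annotations

#: reported (delta AICc, Akaike weight) per growth law for the chronically
#: irradiated yeast chemostat data, best-supported first.
YEAST_MODEL_RANKING: dict[str, tuple[float, float]] = {
    "M1": (0.00, 0.544),
    "M2": (3.37, 0.096),
    "M3": (3.83, 0.076),
    "M4": (4.08, 0.067),
    "M5": (4.74, 0.048),
    "M6": (5.29, 0.037),
    "M7": (5.44, 0.034),
    "M8": (5.52, 0.033),
    "M9": (5.81, 0.028),
    "M10": (7.02, 0.015),
    "M11": (8.68, 0.007),
    "M12": (8.72, 0.007),
    "M13": (9.91, 0.004),
    "M14": (10.07, 0.003),
    "M15": (12.21, 0.001),
    "M16": (12.75, 0.001),
    "M17": (18.61, 0.000),
    "M18": (23.17, 0.000),
    "M19": (26.86, 0.000),
    "M20": (33.28, 0.000),
}

#: models in which radiation and/or dilution affect intraspecific competition
COMPETITION_EFFECT_MODELS = ("M2", "M7", "M10", "M11", "M12", "M14", "M15")

#: models containing a dilution x radiation interaction term
DILUTION_RADIATION_INTERACTION_MODELS = ("M3", "M5", "M7", "M14", "M15")

#: Penicillium hirsutum detections in the reactor-building fungal survey:
#: (detected_high, absent_high, detected_low, absent_low) over 9 high- and
#: 15 low-dose-rate samples.  The reported cross-product odds ratio is 112.
PENICILLIUM_HIRSUTUM_COUNTS = (8, 1, 1, 14)

#: reported best-fit M1 coefficients for the yeast chemostat data
#: (point estimate, 95% CI low, 95% CI high), in the package's native units.
M1_BEST_FIT = {
    "k": (5.78e-4, 3.14e-4, 9.08e-4),  # Gy^-1
    "delta": (4.78e-2, 3.27e-2, 7.89e-2),  # h/Gy
    "q": (0.599, 0.410, 1.01),  # h^-1
    "m": (2.11e-3, 1.43e-3, 3.68e-3),  # ml/(h x 10^6 cells)
}
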