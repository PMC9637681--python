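"""Published reference values from the cadaver validation experiment.

These are the printed measurements from the knee-arthroplasty cadaver study
this simulator is modelled on: the known (gold standard) vial volumes and
activities, the per-vial percent errors obtained with each
attenuation-correction strategy by the primary observer, the second
observer's repeat of the accurate-model measurement, and the whole-cadaver
total errors.  They are inputs for the exact-arithmetic routines (error
reductions, inter-observer statistics) and for cross-checking the
simulator's qualitative behaviour; they are never produced by this package.
"""
from __future__ import annotations

from .errors import CONCENTRATION, GOLD, TOTAL_ACTIVITY, ErrorRecord, ErrorTable

VIALS = ("reference", "anterior", "mid", "posterior")

#: Known (gold standard) dispensed volumes (mL) and activities (MBq).
KNOWN_VIAL_VOLUME_ML = {
    "reference": 1.52, "anterior": 1.53, "mid": 1.56, "posterior": 1.57,
}
KNOWN_VIAL_ACTIVITY_MBQ = {
    "reference": 1.15, "anterior": 1.16, "mid": 1.18, "posterior": 1.19,
}

#: Whole-cadaver total-activity percent error vs gold standard, per strategy.
TOTAL_ERROR_VS_STANDARD = {
    "original": -64.15,
    "simple_tissue": -26.51,
    "model_alternative": 14.56,
    "model_accurate": 3.55,
}

#: Per-vial percent errors vs gold standard (primary observer):
#: strategy -> quantity -> vial -> percent error.
VIAL_ERRORS_VS_STANDARD = {
    "original": {
        TOTAL_ACTIVITY: {"reference": -41.2, "anterior": -59.0, "mid": -83.3, "posterior": -66.8},
        CONCENTRATION: {"reference": -40.2, "anterior": -59.0, "mid": -83.0, "posterior": -66.2},
    },
    "simple_tissue": {
        TOTAL_ACTIVITY: {"reference": -11.3, "anterior": -19.6, "mid": -44.1, "posterior": -42.8},
        CONCENTRATION: {"reference": -9.62, "anterior": -18.5, "mid": -42.9, "posterior": -40.3},
    },
    "model_alternative": {
        TOTAL_ACTIVITY: {"reference": 2.59, "anterior": -12.3, "mid": 2.33, "posterior": -1.66},
        CONCENTRATION: {"reference": 4.56, "anterior": -11.17, "mid": 4.49, "posterior": 2.63},
    },
    "model_accurate": {
        TOTAL_ACTIVITY: {"reference": -6.99, "anterior": -6.26, "mid": -16.8, "posterior": -5.17},
        CONCENTRATION: {"reference": -5.20, "anterior": -5.05, "mid": -15.0, "posterior": -1.02},
    },
}

#: Second observer's repeat with the accurate-model map: quantity -> vial -> error.
SECOND_OBSERVER_ACCURATE = {
    TOTAL_ACTIVITY: {"reference": 3.10, "anterior": -1.35, "mid": -6.83, "posterior": -5.67},
    CONCENTRATION: {"reference": 3.23, "anterior": -1.79, "mid": -4.18, "posterior": -1.56},
}


def known_totals() -> dict[str, float]:
    """Sums and ratio of the known vial volumes and activities."""
    total_ml = sum(KNOWN_VIAL_VOLUME_ML.values())
    total_mbq = sum(KNOWN_VIAL_ACTIVITY_MBQ.values())
    return {
        "total_volume_ml": total_ml,
        "total_activity_mbq": total_mbq,
        "mean_concentration_mbq_per_ml": total_mbq / total_ml,
    }


def as_error_table() -> ErrorTable:
    """The published per-vial gold-standard errors as an :class:`ErrorTable`."""
    table = ErrorTable()
    for strategy, by_quantity in VIAL_ERRORS_VS_STANDARD.items():
        for quantity, by_vial in by_quantity.items():
            for vial, err in by_vial.items():
                table.add(strategy, ErrorRecord(vial, GOLD, quantity, err))
        table.add(strategy, ErrorRecord(
            "total", GOLD, TOTAL_ACTIVITY, TOTAL_ERROR_VS_STANDARD[strategy]))
    return table


def observer_error_lists(quantity: str) -> tuple[list[float], list[float]]:
    """Aligned per-vial accurate-model errors for observer 1 and observer 2."""
    obs1 = [VIAL_ERRORS_VS_STANDARD["model_accurate"][quantity][v] for v in VIALS]
    obs2 = [SECOND_OBSERVER_ACCURATE[quantity][v] for v in VIALS]
    return obs1, obs2
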