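"""Published coefficient sets and cohort summary tables.

The three linear pCR scores (SR-PM, CF-PM, C-PM) ship as versioned JSON
fixtures so they can be scored on new inputs without refitting.  The module
also exposes the study's printed group summaries — candidate-feature medians
and the clinical 2x2 counts — which downstream worked examples use as inputs
(e.g. recomputing univariate odds ratios from the contingency counts).
"""
from __future__ import annotations

import json
from importlib import resources

from .models import ModelCoefficients

_MODEL_FILES = {"sr": "srpm.json", "cf": "cfpm.json", "c": "cpm.json"}


def load_published_model(which: str) -> ModelCoefficients:
    """Load one of the published scores by key: ``"sr"``, ``"cf"`` or ``"c"``.

    The returned object's ``linear_score`` input names are the keys of its
    ``coefficients`` map; ``extras["reported_cutoff"]`` carries the ROC
    cutoff reported for that score (metadata only — not re-derivable here).
    """
    try:
        fname = _MODEL_FILES[which]
    except KeyError:
        raise ValueError(f"unknown published model {which!r}; expected one of {sorted(_MODEL_FILES)}")
    path = resources.files("srnapcr.data.published").joinpath(fname)
    payload = json.loads(path.read_text())
    return ModelCoefficients(
        intercept=payload["intercept"],
        coefficients=dict(payload["coefficients"]),
        predictor_kinds=dict(payload["predictor_kinds"]),
        extras={
            "name": payload["name"],
            "version": payload["version"],
            "reported_cutoff": payload["reported_cutoff"],
        },
    )


# Group medians of the three candidate small-RNA features plus the tRF
# sub-classes (normalized reads per million), as (pCR, non-pCR).
FEATURE_MEDIANS: dict[str, tuple[float, float]] = {
    "let7b_isomir": (160.1, 139.1),
    "mir93_isomir": (326.7, 207.4),
    "tsrna_gly_5half": (69.2, 9.1),
    "tsrna_gly_5trf": (57.9, 44.0),
    "tsrna_gly_itrf": (182.7, 56.7),
    "tsrna_gly_group": (269.5, 144.8),
}

# Clinical factor 2x2 counts, cohort of 30 pCR / 69 non-pCR patients.
# Layout: (exposed_case, exposed_noncase, unexposed_case, unexposed_noncase)
# with "case" = pCR and "exposed" = the named category.
CLINICAL_2X2: dict[str, tuple[int, int, int, int]] = {
    "cT3-4": (26, 59, 4, 10),
    "cN1-3": (21, 55, 9, 14),
    "cM1(LYM)": (6, 9, 24, 60),
    "overall_cCR": (12, 15, 18, 54),
    "biopsy_positive": (0, 11, 30, 58),
}

COHORT_SIZES = {"pCR": 30, "non-pCR": 69}
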