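"""Closed vocabularies shared across the pipeline.

Region and metric labels follow the 11-region / 6-metric scheme used for
regional sampling of the neonatal cortex and the matched prenatal expression
atlas. All ages are handled in postconceptional days internally; imaging
metadata expressed in weeks is converted at ingestion (x7).
"""

from __future__ import annotations

REGIONS: tuple[str, ...] = (
    "A1C", "DLPFC", "IPC", "ITC", "M1", "MFC",
    "OFC", "S1", "STC", "V1", "VLPFC",
)

METRICS: tuple[str, ...] = ("thickness", "t1t2", "FA", "MD", "fICVF", "ODI")

GROUPS: tuple[str, ...] = ("term", "preterm")
HEMISPHERES: tuple[str, ...] = ("L", "R")

# Default planted axis: primary sensorimotor regions at one extreme,
# higher-order association cortex at the other. Configuration values, not
# measurements; mean ~0 so they behave like centred component scores.
DEFAULT_REGION_SCORES: dict[str, float] = {
    "A1C": -2.2,
    "S1": -2.0,
    "M1": -1.8,
    "MFC": -0.8,
    "STC": -0.5,
    "V1": 0.1,
    "DLPFC": 1.2,
    "VLPFC": 1.4,
    "OFC": 1.5,
    "IPC": 1.9,
    "ITC": 2.2,
}

# Cell classes with lineage and maturational-timing annotations used by the
# catalog generator and the enrichment module.
DEFAULT_CELL_CLASSES: dict[str, dict[str, str]] = {
    "astrocyte": {"lineage": "glial", "timing": "mature"},
    "endothelial": {"lineage": "other", "timing": "mature"},
    "microglia": {"lineage": "glial", "timing": "mature"},
    "neuron_excitatory": {"lineage": "neuronal", "timing": "mature"},
    "neuron_inhibitory": {"lineage": "neuronal", "timing": "mature"},
    "oligodendrocyte": {"lineage": "glial", "timing": "mature"},
    "OPC": {"lineage": "glial", "timing": "precursor"},
    "pericyte": {"lineage": "other", "timing": "mature"},
    "intermediate_progenitor": {"lineage": "neuronal", "timing": "precursor"},
    "radial_glia": {"lineage": "glial", "timing": "precursor"},
}

DAYS_PER_WEEK = 7.0


def weeks_to_days(weeks: float) -> float:
    return weeks * DAYS_PER_WEEK
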