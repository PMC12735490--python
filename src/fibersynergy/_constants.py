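"""Shared label vocabulary for the fermentation tables."""

#: The three measured short-chain fatty acids, in reporting order.
ACIDS = ("acetate", "propionate", "butyrate")

#: Derived total = acetate + propionate + butyrate.
TOTAL = "total"

#: All SCFA measures carried through the pipeline.
SCFA_TYPES = ACIDS + (TOTAL,)

#: Substrate label for the four-fiber blend.
MIXTURE = "mixture"

#: Default single-fiber substrate labels (apple pectin, barley beta-glucan,
#: fructooligosaccharides, sorghum arabinoxylan).
DEFAULT_FIBERS = ("pectin", "beta_glucan", "fos", "arabinoxylan")

#: Default donor counts per health condition (healthy controls, Parkinson's
#: disease, Crohn's disease, ulcerative colitis).
DEFAULT_CONDITIONS = {"HC": 10, "PD": 10, "CD": 7, "UC": 7}

#: Column schema of the long-format fermentation table.
FERMENTATION_COLUMNS = ("donor_id", "condition", "substrate", "scfa_type", "concentration_mM")

#: Column schema of the per-sample metadata table.
METADATA_COLUMNS = ("sample_id", "donor_id", "timepoint", "synergy_label")

TIMEPOINTS = ("baseline", "post")
SYNERGY_LABELS = ("synergy", "no_synergy", "unassigned")
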