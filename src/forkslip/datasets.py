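"""Published rate tables for the fission-yeast fork-barrier assay system.

Rates of *ura4* marker loss measured by fluctuation assay (method of the
median) in strains carrying the conditional *RTS1* replication-fork
barrier near *ura4*, with the barrier protein Rtf1 repressed (+thiamine,
barrier OFF) or expressed (-thiamine, barrier ON).  Construct names read
telomere-to-origin: ``<`` and ``>`` mark the barrier and its polarity,
e.g. ``t-ura4<ori`` blocks forks travelling from the origin toward the
telomere just next to *ura4*.

All rates are in units of 1e-8 events/cell/division.  These tables are
inputs for the rate-partition arithmetic (fold inductions, induced
rates, spectrum balancing); the raw per-culture colony counts behind
them are not published, so absolute rates cannot be recomputed from
scratch and are consumed as given.
"""

from __future__ import annotations

__all__ = [
    "URA4_LOSS_RATES",
    "MUTATION_CATEGORY_RATES",
    "CONTROL_STRAIN",
    "RATE_UNIT",
]

#: Scale of every rate in this module (events/cell/division).
RATE_UNIT = 1e-8

#: Barrier-free control construct used for fold-vs-control ratios.
CONTROL_STRAIN = "t-ura4-ori"

#: Total rate of ura4 loss per strain: barrier OFF (+thiamine) and
#: barrier ON (-thiamine), with standard errors, x1e-8.
URA4_LOSS_RATES = {
    "t-ura4-ori": {"off": 4.6, "off_se": 1.0, "on": 4.3, "on_se": 1.8},
    "t-ura4<ori": {"off": 4.1, "off_se": 0.9, "on": 13.9, "on_se": 2.8},
    "t-ura4<ori RTS1-d": {"off": 4.9, "off_se": 1.4, "on": 11.4, "on_se": 4.1},
    "t<ura4-ori": {"off": 3.9, "off_se": 1.3, "on": 4.8, "on_se": 2.5},
    "t>ura4<ori": {"off": 5.8, "off_se": 2.1, "on": 97.4, "on_se": 51.5},
    "t>ura4<ori RTS1-d": {"off": 4.9, "off_se": 2.2, "on": 19.5, "on_se": 3.3},
    "t>ura4-ori": {"off": 3.2, "off_se": 1.7, "on": 3.6, "on_se": 1.8},
    "t<ura4>ori": {"off": 6.6, "off_se": 1.7, "on": 50.3, "on_se": 14.2},
}

#: Balanced mutation-category rates (base substitutions, frameshifts,
#: deletions/duplications between short tandem repeats), x1e-8, for the
#: strains whose spectra were sequenced.  OFF = Rtf1 repressed,
#: ON = Rtf1 expressed (fork arrest at ura4 where the construct allows).
MUTATION_CATEGORY_RATES = {
    "t-ura4<ori": {
        "OFF": {"base_substitution": 3.4, "frameshift": 0.2, "del_dup": 0.7},
        "ON": {"base_substitution": 6.4, "frameshift": 1.0, "del_dup": 4.9},
    },
    "t-ura4<ori rad22-d": {
        "OFF": {"base_substitution": 115.0, "frameshift": 8.7, "del_dup": 3.7},
        "ON": {"base_substitution": 152.0, "frameshift": 20.4, "del_dup": 13.0},
    },
}
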