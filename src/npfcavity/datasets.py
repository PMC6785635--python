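"""Packaged reference tables: NPF roster, GA registry, anchors, screen summary.

These are small plain-text tables shipped with the package:

* ``npf_roster.tsv`` — the 53 Arabidopsis NPF members and their subclade under
  the unified NPF nomenclature.
* ``ga_compounds.tsv`` — gibberellin registry: molecular formula (oxygen
  counts are derived from it at load time), default pKa and nominal external
  assay concentration.
* ``cavity_anchors.tsv`` — the cavity position labels recoverable from the
  published analysis, anchored to NPF6.3 residue numbers (14 of the 51
  positions; the remainder require the full supplementary position list and
  are deliberately not guessed).
* ``screen_fixture.tsv`` — a transcription of the published screen outcome at
  the transporter × compound level (normalized activity and significance
  flags); replicate-level data were not published, so this is a summary
  table, not raw data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .iontrap import classify_permeability, oxygen_count_from_formula


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("npfcavity.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_npf_roster() -> pd.DataFrame:
    """The 53 Arabidopsis NPF transporters with subclade annotation."""
    return _read("npf_roster.tsv")


def load_ga_compounds() -> pd.DataFrame:
    """Gibberellin registry with oxygen counts and permeability classes
    computed from the stored molecular formulas."""
    table = _read("ga_compounds.tsv")
    table["oxygen_count"] = table["formula"].map(oxygen_count_from_formula)
    table["permeability_class"] = table["oxygen_count"].map(classify_permeability)
    return table


def load_cavity_anchors() -> dict[str, int]:
    """Cavity position labels → NPF6.3 residue numbers (the 14 published anchors)."""
    table = _read("cavity_anchors.tsv")
    return dict(zip(table["position"], table["residue_number"].astype(int)))


def load_screen_fixture() -> pd.DataFrame:
    """Transporter × compound screen summary (normalized activity, significance)."""
    table = _read("screen_fixture.tsv")
    table["significant"] = table["significant"].astype(bool)
    return table


def compound_class_map() -> dict[str, str]:
    """Compound name → permeability class for the packaged registry."""
    table = load_ga_compounds()
    return dict(zip(table["name"], table["permeability_class"]))
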