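"""Bundled reference data."""

from importlib import resources

from .screening_stats import ToxicityTable


def reference_survival_table() -> ToxicityTable:
    """The published 48-h dose-survival table of the eight test compounds.

    Mean % survival of normal zebrafish larvae after 48 h of exposure,
    re-entered from the printed table (concentration grid 0.125-10 µM,
    n = 10 per condition, three independent experiments).
    """
    path = resources.files("xenoscreen").joinpath("data/table1_survival.csv")
    with resources.as_file(path) as p:
        return ToxicityTable.from_csv(p)
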