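"""Access to the reference data shipped with the package.

``reference_review_panel`` returns the 83 re-reviewed CNV records from a
published nine-laboratory classification comparison (82 initially discordant
plus one force-reviewed deletion), expanded from the published
pattern-by-pattern counts. ``reference_rates`` returns the published
numerator/denominator tallies for the same study's panels.
"""

from __future__ import annotations

import json
from importlib import resources

from .audit import ReviewRecord
from .io import read_review_records

__all__ = ["reference_review_panel", "reference_rates"]


def _data_path(name: str):
    return resources.files("cnvscore.data").joinpath(name)


def reference_review_panel(include_forced: bool = True) -> list[ReviewRecord]:
    """The shipped multi-laboratory re-review panel (83 records).

    With ``include_forced=False`` the force-reviewed, initially concordant
    deletion is dropped, leaving the 82 initially discordant records.
    """
    with resources.as_file(_data_path("reference_review_panel.tsv")) as p:
        records = read_review_records(p)
    if not include_forced:
        records = [r for r in records if not r.forced_review]
    return records


def reference_rates() -> dict:
    """Published concordance tallies as (numerator, denominator) pairs."""
    return json.loads(_data_path("reference_rates.json").read_text(encoding="utf-8"))
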