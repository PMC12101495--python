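"""Source attribution (presence calls) and apportionment.

A fecal source is called present only when two conditions hold at
once: at least one of its *source-specific* (unflagged) genomes was
detected, and its total estimated cell fraction — specific plus
cross-reactive — strictly exceeds the limit of detection (0.01%
relative abundance by default).  Signal carried only by cross-reactive
genomes is therefore disregarded, however large.

Apportionment then divides each present source's total cell fraction
by the summed cell fractions of all present sources, so the portions
sum to one and are invariant to any uniform rescaling of the
fractions (an error in the GEQ cancels).  The environmental screen
category never receives a portion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geq import CellFractionTable

REASON_PRESENT = "specific_and_above_lod"
REASON_BELOW_LOD = "below_lod"
REASON_NO_SPECIFIC = "no_specific_genome"
REASON_SCREEN = "screen_excluded"

DEFAULT_LOD_PERCENT = 0.01


@dataclass(frozen=True)
class SourceCall:
    category: str
    present: bool
    reason: str

    def __post_init__(self) -> None:
        if self.present and self.reason != REASON_PRESENT:
            raise ValueError("present calls must carry the present reason")


@dataclass
class SampleReport:
    sample_id: str
    calls: list[SourceCall]
    cell_fractions: CellFractionTable
    portions: dict[str, float]
    lod_percent: float

    def call(self, category: str) -> SourceCall:
        return next(c for c in self.calls if c.category == category)

    def present_categories(self) -> list[str]:
        return [c.category for c in self.calls if c.present]

    def write_tsv(self, attribution_path, apportionment_path) -> None:
        with open(attribution_path, "w") as fh:
            fh.write("sample\tcategory\tpresent\treason\tcell_fraction\tn_specific\n")
            for c in self.calls:
                f = self.cell_fractions.fractions[c.category]
                fh.write(
                    f"{self.sample_id}\t{c.category}\t{c.present}\t{c.reason}\t"
                    f"{f.cell_fraction:.8g}\t{f.n_specific_detected}\n"
                )
        with open(apportionment_path, "w") as fh:
            fh.write("sample\tcategory\tportion\n")
            for cat, portion in self.portions.items():
                fh.write(f"{self.sample_id}\t{cat}\t{portion:.8g}\n")


def attribute(
    fractions: CellFractionTable,
    lod_percent: float = DEFAULT_LOD_PERCENT,
) -> list[SourceCall]:
    """Apply the two-condition presence logic to every category.

    The LOD is in percent relative abundance and the comparison is
    strict (the fraction must *exceed* it); the specific-genome
    condition is evaluated first when assigning an absence reason.
    """
    calls = []
    for f in fractions.fractions.values():
        if f.is_screen:
            calls.append(SourceCall(f.category, False, REASON_SCREEN))
        elif f.n_specific_detected < 1:
            calls.append(SourceCall(f.category, False, REASON_NO_SPECIFIC))
        elif f.cell_fraction * 100.0 > lod_percent:
            calls.append(SourceCall(f.category, True, REASON_PRESENT))
        else:
            calls.append(SourceCall(f.category, False, REASON_BELOW_LOD))
    return calls


def apportion(
    fractions: CellFractionTable,
    calls: list[SourceCall],
) -> dict[str, float]:
    """Portions of the total detected fecal signal per present source.

    portion_j = cell_fraction_j / sum over present fecal sources; a
    present source's full fraction (specific plus cross-reactive)
    counts.  Returns an empty map when nothing is present.
    """
    present = [c.category for c in calls if c.present]
    total = sum(fractions.fractions[cat].cell_fraction for cat in present)
    if not present or total <= 0:
        return {}
    return {
        cat: fractions.fractions[cat].cell_fraction / total for cat in present
    }


def report(
    fractions: CellFractionTable,
    lod_percent: float = DEFAULT_LOD_PERCENT,
) -> SampleReport:
    """Attribution plus apportionment in one report."""
    calls = attribute(fractions, lod_percent)
    return SampleReport(
        sample_id=fractions.sample_id,
        calls=calls,
        cell_fractions=fractions,
        portions=apportion(fractions, calls),
        lod_percent=lod_percent,
    )
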