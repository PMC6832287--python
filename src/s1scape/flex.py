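"""Per-residue flexibility classification and percent-flexible summaries.

Two sources are supported:

* predicted per-residue fluctuation tables (Å), classified with fixed
  thresholds: < 3 rigid, 3-6 moderate (boundaries inclusive), > 6 flexible;
* crystallographic B-factors, converted to within-domain z-scores over CA
  B-factors and classified as flexible (z > 1), moderate (0 <= z <= 1) or
  rigid (z < 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from s1scape.structure import Structure

RIGID = "rigid"
MODERATE = "moderate"
FLEXIBLE = "flexible"

FLUCT_RIGID_MAX = 3.0  # Å, exclusive
FLUCT_FLEX_MIN = 6.0  # Å, exclusive


class FlexError(ValueError):
    pass


@dataclass
class FlexProfile:
    residue_numbers: list[int]
    values: np.ndarray
    source: str  # "predicted" | "bfactor"
    labels: list[str]
    warning: str | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise FlexError("labels and values length mismatch")

    @property
    def percent_flexible(self) -> float:
        return percent_flexible(self.labels)


def classify_fluctuations(values) -> list[str]:
    """Three-class labels from predicted fluctuations in Å."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise FlexError("fluctuation values must be >= 0")
    labels = []
    for v in values:
        if v < FLUCT_RIGID_MAX:
            labels.append(RIGID)
        elif v <= FLUCT_FLEX_MIN:
            labels.append(MODERATE)
        else:
            labels.append(FLEXIBLE)
    return labels


def percent_flexible(labels, include_moderate: bool = False) -> float:
    """Percentage of residues labeled flexible (optionally + moderate)."""
    labels = list(labels)
    if not labels:
        raise FlexError("empty label list")
    wanted = {FLEXIBLE, MODERATE} if include_moderate else {FLEXIBLE}
    return 100.0 * sum(1 for x in labels if x in wanted) / len(labels)


def predicted_profile(residue_numbers, values) -> FlexProfile:
    values = np.asarray(values, dtype=float)
    return FlexProfile(
        residue_numbers=list(residue_numbers),
        values=values,
        source="predicted",
        labels=classify_fluctuations(values),
    )


def read_fluctuation_table(path: str | Path, expected_length: int | None = None) -> FlexProfile:
    """Read a two-column (residue_number, value) whitespace-separated table.

    A non-numeric first line is treated as a header.  Rows are sorted by
    residue number.  If ``expected_length`` is given and differs, a warning
    is attached to the profile rather than raising.
    """
    rows: list[tuple[int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FlexError(f"{path}: line {lineno}: expected two columns")
            try:
                rows.append((int(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise FlexError(
                    f"{path}: line {lineno}: non-numeric value {line!r}"
                ) from None
    if not rows:
        raise FlexError(f"{path}: no data rows")
    rows.sort(key=lambda rv: rv[0])
    numbers = [r for r, _ in rows]
    values = np.array([v for _, v in rows])
    prof = predicted_profile(numbers, values)
    if expected_length is not None and len(rows) != expected_length:
        prof.warning = (
            f"{path}: {len(rows)} values for a {expected_length}-residue domain"
        )
    return prof


def bfactor_zscores(s: Structure) -> FlexProfile:
    """Within-domain z-scores of CA B-factors (population sd).

    flexible: z > 1; moderate: 0 <= z <= 1; rigid: z < 0.
    """
    numbers, bvals = [], []
    for res in s.residues:
        ca = res.atom("CA")
        if ca is not None:
            numbers.append(res.number)
            bvals.append(ca.b_factor)
    if not bvals:
        raise FlexError("no CA B-factors in structure")
    b = np.asarray(bvals, dtype=float)
    sd = float(b.std())  # population sd
    if sd == 0.0:
        raise FlexError("uninformative B-factors (zero variance)")
    z = (b - b.mean()) / sd
    labels = [FLEXIBLE if v > 1 else (MODERATE if v >= 0 else RIGID) for v in z]
    return FlexProfile(
        residue_numbers=numbers, values=z, source="bfactor", labels=labels
    )
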