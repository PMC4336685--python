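"""Sample metadata: individuals, sexes, pedigree roles, and inline barcodes.

A RAD library multiplexes many individuals in one sequencing lane; each
individual is identified by an 8-nt inline multiplex identifier (MID) at the
start of every read.  The sample sheet is the single source of truth mapping
MID -> individual -> sex/role for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

FEMALE = "female"
MALE = "male"

MID_LENGTH = 8

#: pedigree roles used by the screen
ROLE_MOTHER = "mother"
ROLE_FATHER = "father"
ROLE_PROGENY = "progeny"
ROLE_PANEL = "panel"


@dataclass(frozen=True)
class Individual:
    """One sampled plant/animal with its sex label and pedigree role."""

    individual_id: str
    sex: str
    role: str
    mid: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be {FEMALE!r} or {MALE!r}, got {self.sex!r}")
        if self.role not in (ROLE_MOTHER, ROLE_FATHER, ROLE_PROGENY, ROLE_PANEL):
            raise ValueError(f"unknown role {self.role!r}")


def validate_mids(individuals: list[Individual], min_distance: int = 3) -> None:
    """Check that all MIDs are 8 nt, unique and pairwise Hamming >= min_distance.

    Exact-match demultiplexing is only unambiguous when barcodes are spaced
    apart; distance >= 3 additionally makes 1-mismatch rescue safe.
    """
    mids = [ind.mid for ind in individuals]
    if any(m is None for m in mids):
        raise ValueError("every individual needs a MID barcode")
    for m in mids:
        if len(m) != MID_LENGTH or set(m) - set("ACGT"):
            raise ValueError(f"MID {m!r} is not an {MID_LENGTH}-nt ACGT string")
    if len(set(mids)) != len(mids):
        raise ValueError("duplicate MID in sample sheet")
    for i, a in enumerate(mids):
        for b in mids[i + 1:]:
            d = sum(x != y for x, y in zip(a, b))
            if d < min_distance:
                raise ValueError(
                    f"MIDs {a} and {b} are only {d} mismatches apart "
                    f"(need >= {min_distance})"
                )


def write_sample_sheet(individuals: list[Individual], path: str | Path) -> None:
    df = pd.DataFrame(
        [(i.individual_id, i.sex, i.role, i.mid) for i in individuals],
        columns=["individual_id", "sex", "role", "MID"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[Individual]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "sex", "role", "MID"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return [
        Individual(r.individual_id, r.sex, r.role, r.MID)
        for r in df.itertuples(index=False)
    ]


def sexes_of(individuals: list[Individual]) -> dict[str, str]:
    """Mapping individual_id -> sex for screen input."""
    return {i.individual_id: i.sex for i in individuals}
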