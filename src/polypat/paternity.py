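"""Paternity assignment from biallelic SNP calls.

For each offspring the maternal genotype is known (seeds are harvested per
plant), and every candidate father is homozygous at the assignment markers.
At each marker the base belonging to the maternal genotype is identified and
the other base is attributed to the paternal genotype. The paternal base
vector is then matched against the candidate signatures:

* level 0 -- exact match on all markers (no missing calls); unique -> assigned;
* level 1 -- every way of ignoring one position (missing positions consume
  the budget first); if the union of matching candidates over all ignored
  subsets is a single genotype -> assigned with n_ignored = 1;
* level 2 -- likewise with two ignored positions;
* otherwise the seed is unassigned.

If two or more distinct candidates appear in the union at the deciding
level, the seed is ambiguous (the conservative reading of "matched a unique
genotype"). Seeds whose calls contradict the maternal genotype are looked up
in an optional resample table (a second genotyping run); a persistent
mismatch omits the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, PanelError
from .panel import GenotypePanel, paternal_signature

MISSING = "*missing*"
MISMATCH = "*mismatch*"

STATUS_ASSIGNED = "assigned"
STATUS_MATERNAL_MISMATCH = "maternal_mismatch"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class FatherAssignment:
    seed_id: Optional[str]
    status: str
    father_genotype: Optional[str] = None
    n_ignored: int = 0
    ignored_markers: tuple = ()

    def __post_init__(self):
        if (self.status == STATUS_ASSIGNED) != (self.father_genotype is not None):
            raise DataError("status 'assigned' iff a father is present")


def infer_paternal_allele(offspring_call, maternal_base: str):
    """Attribute one base of the offspring call to the father.

    ``offspring_call`` is an unordered base pair or ``None`` (missing call).
    Returns the paternal base, or :data:`MISSING` / :data:`MISMATCH`.
    A mismatch (neither base maternal) is a value, not an exception: it feeds
    the resample-or-omit rule.
    """
    if offspring_call is None:
        return MISSING
    a, b = offspring_call
    if a == maternal_base:
        return b
    if b == maternal_base:
        return a
    return MISMATCH


def match_father(
    paternal_vector: Sequence[str],
    candidates: Mapping[str, Sequence[str]],
    max_ignored: int = 2,
    marker_ids: Optional[Sequence[str]] = None,
    seed_id: Optional[str] = None,
) -> FatherAssignment:
    """Match a paternal base vector against candidate signatures.

    Missing positions consume the ignore budget before any observed base may
    be dropped; levels are tried strictly in order 0, 1, ... ``max_ignored``
    and the first decisive level wins.
    """
    n = len(paternal_vector)
    if marker_ids is None:
        marker_ids = [str(i) for i in range(n)]
    for name, sig in candidates.items():
        if len(sig) != n:
            raise DataError(f"candidate {name} signature length != vector length")

    missing = [i for i, b in enumerate(paternal_vector) if b == MISSING]
    observed = [i for i in range(n) if i not in missing]
    if len(missing) > max_ignored:
        return FatherAssignment(seed_id, STATUS_UNASSIGNED)

    def matches(kept: Sequence[int]) -> list:
        return [
            name
            for name, sig in candidates.items()
            if all(sig[i] == paternal_vector[i] for i in kept)
        ]

    for level in range(len(missing), max_ignored + 1):
        union: dict = {}
        n_extra = level - len(missing)
        for extra in itertools.combinations(observed, n_extra):
            kept = [i for i in observed if i not in extra]
            for name in matches(kept):
                union.setdefault(name, tuple(missing) + extra)
        if len(union) == 1:
            (name, ignored), = union.items()
            return FatherAssignment(
                seed_id,
                STATUS_ASSIGNED,
                father_genotype=name,
                n_ignored=level,
                ignored_markers=tuple(marker_ids[i] for i in sorted(ignored)),
            )
        if len(union) >= 2:
            return FatherAssignment(seed_id, STATUS_AMBIGUOUS, n_ignored=level)
    return FatherAssignment(seed_id, STATUS_UNASSIGNED)


@dataclass(frozen=True)
class SeedClass:
    kind: str  # "self_or_intra" | "inter"
    donor: Optional[str] = None


def classify_seed(assignment: FatherAssignment, mother_genotype: str) -> SeedClass:
    """Self-or-intra vs inter-genotype cross; only assigned seeds classify."""
    if assignment.status != STATUS_ASSIGNED:
        raise DataError(f"cannot classify a seed with status {assignment.status!r}")
    if assignment.father_genotype == mother_genotype:
        return SeedClass("self_or_intra")
    return SeedClass("inter", donor=assignment.father_genotype)


def confirm_f1_hybrid(
    f1, parent1, parent2, confirmation_markers: Sequence[str]
) -> bool:
    """True iff the putative F1 is heterozygous at every confirmation marker.

    Each confirmation marker must be informative: the (homozygous) parents
    must carry different bases there.
    """
    for mid in confirmation_markers:
        b1 = parent1.homozygous_base(mid)
        b2 = parent2.homozygous_base(mid)
        if b1 == b2:
            raise PanelError(
                f"confirmation marker {mid} is uninformative: both parents "
                f"carry {b1}"
            )
        call = f1.call(mid)
        if call is None or call[0] == call[1]:
            return False
        if set(call) != {b1, b2}:
            return False
    return True


# ---------------------------------------------------------------------------
# Batch assignment
# ---------------------------------------------------------------------------

def _parse_call_cell(text: str):
    if text in ("NA", "", None) or (isinstance(text, float) and np.isnan(text)):
        return None
    a, _, b = str(text).partition("/")
    return (a, b) if a <= b else (b, a)


def _paternal_row(row, markers, maternal_bases):
    return [
        infer_paternal_allele(_parse_call_cell(row[mid]), maternal_bases[mid])
        for mid in markers
    ]


def assign_batch(
    calls: pd.DataFrame,
    panel: GenotypePanel,
    mother_map: Mapping[str, str],
    resample_table: Optional[pd.DataFrame] = None,
    max_ignored: int = 2,
    markers: Optional[Sequence[str]] = None,
) -> tuple:
    """Assign fathers to a batch of offspring call rows.

    ``mother_map`` maps mother plant ids to maternal genotype ids.
    ``resample_table`` is a second call table keyed by ``seed_id``; it is
    consulted when the first run contradicts the maternal genotype, and a
    seed absent from it (or still mismatching) is omitted as
    ``maternal_mismatch``.

    Returns ``(assignments, summary)``: per-seed assignment rows and a
    per-genotype summary with the identification rate (assigned / sampled;
    NA for zero sampled seeds).
    """
    if markers is None:
        markers = panel.assignment_markers
    markers = list(markers)
    if not markers:
        raise DataError("no assignment markers")

    candidates = {
        g.genotype_id: paternal_signature(g, markers) for g in panel.genotypes
    }
    maternal = {
        g.genotype_id: {mid: g.homozygous_base(mid) for mid in markers}
        for g in panel.genotypes
    }
    for plant in calls["mother_plant"].unique():
        if plant not in mother_map:
            raise DataError(f"mother plant {plant!r} absent from mother map")
        panel.genotype(mother_map[plant])  # mother genotype must exist

    resample = None
    if resample_table is not None:
        resample = resample_table.set_index("seed_id")

    sig_arr = {name: np.array(sig) for name, sig in candidates.items()}
    mg_col = calls["mother_plant"].map(mother_map)

    # vectorized paternal-base matrix
    pat = np.empty((len(calls), len(markers)), dtype=object)
    for j, mid in enumerate(markers):
        col = calls[mid].to_numpy(dtype=object)
        for i, (text, mg) in enumerate(zip(col, mg_col)):
            pat[i, j] = infer_paternal_allele(
                _parse_call_cell(text), maternal[mg][mid]
            )

    records = []
    for i, (seed_id, mg) in enumerate(zip(calls["seed_id"], mg_col)):
        vec = list(pat[i])
        if MISMATCH in vec:
            vec = None
            if resample is not None and seed_id in resample.index:
                row = resample.loc[seed_id]
                revec = _paternal_row(row, markers, maternal[mg])
                if MISMATCH not in revec:
                    vec = revec
            if vec is None:
                a = FatherAssignment(seed_id, STATUS_MATERNAL_MISMATCH)
                records.append((a, mg))
                continue
        a = match_father(
            vec, candidates, max_ignored=max_ignored,
            marker_ids=markers, seed_id=seed_id,
        )
        records.append((a, mg))

    assignments = pd.DataFrame(
        {
            "seed_id": calls["seed_id"].to_numpy(),
            "mother_genotype": [mg for _, mg in records],
            "block": calls["block"].to_numpy(),
            "year": calls["year"].to_numpy(),
            "status": [a.status for a, _ in records],
            "father_genotype": [a.father_genotype or "NA" for a, _ in records],
            "n_ignored": [a.n_ignored for a, _ in records],
        }
    )
    summary = summarize_assignments(assignments, panel.genotype_ids)
    return assignments, summary


def summarize_assignments(
    assignments: pd.DataFrame, genotype_ids: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for gid in list(genotype_ids) + ["ALL"]:
        sub = (
            assignments
            if gid == "ALL"
            else assignments[assignments["mother_genotype"] == gid]
        )
        sampled = len(sub)
        assigned = int((sub["status"] == STATUS_ASSIGNED).sum())
        rate = assigned / sampled if sampled else np.nan
        rows.append((gid, sampled, assigned, rate))
    return pd.DataFrame(
        rows, columns=["mother_genotype", "sampled", "assigned", "identification_rate"]
    )


def write_assignments(assignments: pd.DataFrame, path) -> None:
    assignments.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"seed_id": str, "father_genotype": str})
    needed = {"seed_id", "mother_genotype", "block", "year", "status",
              "father_genotype"}
    missing = needed - set(df.columns)
    if missing:
        raise DataError(f"assignments table lacks columns {sorted(missing)}")
    return df
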