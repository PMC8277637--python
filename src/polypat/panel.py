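"""SNP panels of candidate parents.

A panel lists biallelic SNP markers and the genotype calls of every candidate
pollen donor. Paternity testing relies on three disjoint marker sets:

* ``id_set`` -- the minimal marker subset on which the homozygous signatures
  of all candidates are pairwise distinct,
* ``validation_set`` -- a second, disjoint subset that is distinguishing on
  its own,
* ``confirmation_set`` -- markers at which manually produced F1 hybrids are
  heterozygous, used only to confirm hybridity.

All candidates (inbred lines and F1 hybrids alike) must be homozygous on
``id_set`` and ``validation_set`` so the same matching algorithm applies to
both classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import InfeasibleMarkerSet, PanelError

VALID_BASES = frozenset("ACGT")
GENOTYPE_CLASSES = ("inbred", "F1")

Call = Optional[tuple[str, str]]


@dataclass(frozen=True)
class SNPMarker:
    """A biallelic SNP with exactly two distinct alleles."""

    marker_id: str
    alleles: frozenset

    def __post_init__(self):
        alleles = frozenset(self.alleles)
        object.__setattr__(self, "alleles", alleles)
        if len(alleles) != 2 or not alleles <= VALID_BASES:
            raise PanelError(
                f"marker {self.marker_id!r}: need exactly two distinct bases "
                f"from A/C/G/T, got {sorted(alleles)}"
            )

    @property
    def allele_pair(self) -> tuple[str, str]:
        a, b = sorted(self.alleles)
        return a, b

    def other_allele(self, base: str) -> str:
        a, b = self.allele_pair
        if base == a:
            return b
        if base == b:
            return a
        raise PanelError(f"base {base!r} is not an allele of {self.marker_id}")


@dataclass
class GenotypeRecord:
    """Calls of one candidate parent at the panel's markers.

    ``calls`` maps marker_id to an alphabetically ordered base pair, or to
    ``None`` for a missing call.
    """

    genotype_id: str
    genotype_class: str = "inbred"
    parent1: Optional[str] = None
    parent2: Optional[str] = None
    calls: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise PanelError(
                f"{self.genotype_id}: unknown class {self.genotype_class!r}"
            )
        if self.genotype_class == "F1" and not (self.parent1 and self.parent2):
            raise PanelError(f"{self.genotype_id}: F1 records need both parent ids")
        norm = {}
        for mid, call in self.calls.items():
            if call is None:
                norm[mid] = None
            else:
                x, y = call
                norm[mid] = (x, y) if x <= y else (y, x)
        self.calls = norm

    def call(self, marker_id: str) -> Call:
        return self.calls.get(marker_id)

    def is_homozygous(self, marker_id: str) -> bool:
        c = self.call(marker_id)
        return c is not None and c[0] == c[1]

    def homozygous_base(self, marker_id: str) -> str:
        c = self.call(marker_id)
        if c is None:
            raise PanelError(f"{self.genotype_id}: missing call at {marker_id}")
        if c[0] != c[1]:
            raise PanelError(
                f"{self.genotype_id}: heterozygous at {marker_id} ({c[0]}/{c[1]})"
            )
        return c[0]


@dataclass
class GenotypePanel:
    markers: list
    genotypes: list
    id_set: list = field(default_factory=list)
    validation_set: list = field(default_factory=list)
    confirmation_set: list = field(default_factory=list)

    def __post_init__(self):
        self._markers_by_id = {m.marker_id: m for m in self.markers}
        if len(self._markers_by_id) != len(self.markers):
            raise PanelError("duplicate marker ids in panel")
        self._genotypes_by_id = {g.genotype_id: g for g in self.genotypes}
        if len(self._genotypes_by_id) != len(self.genotypes):
            raise PanelError("duplicate genotype ids in panel")

    # -- lookups ---------------------------------------------------------
    @property
    def marker_ids(self) -> list:
        return [m.marker_id for m in self.markers]

    @property
    def genotype_ids(self) -> list:
        return [g.genotype_id for g in self.genotypes]

    def marker(self, marker_id: str) -> SNPMarker:
        try:
            return self._markers_by_id[marker_id]
        except KeyError:
            raise PanelError(f"unknown marker {marker_id!r}") from None

    def genotype(self, genotype_id: str) -> GenotypeRecord:
        try:
            return self._genotypes_by_id[genotype_id]
        except KeyError:
            raise PanelError(f"unknown genotype {genotype_id!r}") from None

    @property
    def assignment_markers(self) -> list:
        """Markers used for paternity matching: id_set followed by validation_set."""
        return list(self.id_set) + list(self.validation_set)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise PanelError on any violated panel invariant."""
        sets = [set(self.id_set), set(self.validation_set), set(self.confirmation_set)]
        for a, b in itertools.combinations(range(3), 2):
            if sets[a] & sets[b]:
                raise PanelError(
                    f"marker sets overlap: {sorted(sets[a] & sets[b])}"
                )
        for s in sets:
            for mid in s:
                self.marker(mid)  # must exist
        for g in self.genotypes:
            for mid, call in g.calls.items():
                if call is None:
                    continue
                marker = self.marker(mid)
                for base in call:
                    if base not in marker.alleles:
                        raise PanelError(
                            f"{g.genotype_id} at {mid}: call {call[0]}/{call[1]} "
                            f"uses base outside alleles "
                            f"{marker.allele_pair[0]}/{marker.allele_pair[1]}"
                        )
            for mid in self.assignment_markers:
                if not g.is_homozygous(mid):
                    raise PanelError(
                        f"{g.genotype_id} must be homozygous at id/validation "
                        f"marker {mid}"
                    )
        if self.assignment_markers and len(self.genotypes) >= 2:
            if not distinguishes(self, self.genotype_ids, self.assignment_markers):
                raise PanelError(
                    "id_set + validation_set do not distinguish all genotypes"
                )


def paternal_signature(genotype: GenotypeRecord, subset: Sequence[str]) -> tuple:
    """One base per marker for a genotype homozygous on ``subset``."""
    return tuple(genotype.homozygous_base(mid) for mid in subset)


def distinguishes(
    panel: GenotypePanel, candidates: Sequence[str], subset: Sequence[str]
) -> bool:
    """True iff candidate signatures on ``subset`` are pairwise distinct."""
    sigs = [paternal_signature(panel.genotype(c), subset) for c in candidates]
    return len(set(sigs)) == len(sigs)


def eligible_markers(panel: GenotypePanel, candidates: Sequence[str]) -> list:
    """Markers at which every candidate is homozygous (non-missing).

    Only such markers can enter the id or validation set: the matching
    algorithm treats all candidates (including F1 hybrids) via their single
    homozygous base.
    """
    out = []
    for m in panel.markers:
        if all(panel.genotype(c).is_homozygous(m.marker_id) for c in candidates):
            out.append(m.marker_id)
    return out


def _first_distinguishing(
    panel: GenotypePanel,
    candidates: Sequence[str],
    pool: Sequence[str],
    size: int,
) -> Optional[list]:
    # pool sorted -> itertools.combinations yields subsets in lexicographic
    # order, so the first hit is the deterministic (lexicographically
    # smallest) optimum.
    for subset in itertools.combinations(sorted(pool), size):
        if distinguishes(panel, candidates, subset):
            return list(subset)
    return None


def minimal_distinguishing_set(
    panel: GenotypePanel, candidates: Optional[Sequence[str]] = None
) -> list:
    """Smallest marker subset with pairwise-distinct candidate signatures.

    Exhaustive search over subset sizes; ties broken lexicographically on the
    sorted marker-id tuple. At panel scale (<=8 candidates, <=20 markers) the
    enumeration is cheap and exactness beats heuristics.
    """
    if candidates is None:
        candidates = panel.genotype_ids
    if len(candidates) < 2:
        raise PanelError("need at least two candidates to distinguish")
    pool = eligible_markers(panel, candidates)
    for size in range(1, len(pool) + 1):
        found = _first_distinguishing(panel, candidates, pool, size)
        if found is not None:
            return found
    # infeasible: report one colliding pair over all eligible markers
    sigs = {}
    for c in candidates:
        sig = paternal_signature(panel.genotype(c), pool)
        if sig in sigs:
            raise InfeasibleMarkerSet(
                f"candidates {sigs[sig]!r} and {c!r} are identical over all "
                f"{len(pool)} eligible markers"
            )
        sigs[sig] = c
    raise InfeasibleMarkerSet("no distinguishing marker subset exists")


def select_validation_set(
    panel: GenotypePanel,
    primary: Sequence[str],
    k: int = 4,
    candidates: Optional[Sequence[str]] = None,
) -> list:
    """k markers disjoint from ``primary`` that are distinguishing on their own."""
    if candidates is None:
        candidates = panel.genotype_ids
    if k == 0:
        return []
    if not distinguishes(panel, candidates, primary):
        raise PanelError("primary marker set is not distinguishing")
    pool = [m for m in eligible_markers(panel, candidates) if m not in set(primary)]
    if len(pool) < k:
        raise InfeasibleMarkerSet(
            f"only {len(pool)} eligible markers outside the primary set, need {k}"
        )
    found = _first_distinguishing(panel, candidates, pool, k)
    if found is None:
        raise InfeasibleMarkerSet(
            f"no distinguishing {k}-subset disjoint from the primary set exists"
        )
    return found


# ---------------------------------------------------------------------------
# TSV I/O
#
# Format: optional '#marker' preamble lines declaring alleles and set
# membership, then a tab-separated table
#   genotype_id  class  parent1  parent2  <marker_id>...
# with calls 'X/Y' (X<=Y alphabetically) and 'NA' for missing.
# ---------------------------------------------------------------------------

_SET_TAGS = {"id": "id_set", "validation": "validation_set",
             "confirmation": "confirmation_set", "none": None}


def _format_call(call: Call) -> str:
    return "NA" if call is None else f"{call[0]}/{call[1]}"


def _parse_call(text: str, marker: SNPMarker, lineno: int) -> Call:
    if text == "NA":
        return None
    parts = text.split("/")
    if len(parts) != 2 or not all(p in VALID_BASES for p in parts):
        raise PanelError(
            f"line {lineno}: malformed call {text!r} at marker {marker.marker_id}"
        )
    for base in parts:
        if base not in marker.alleles:
            raise PanelError(
                f"line {lineno}: call {text!r} at marker {marker.marker_id} "
                f"uses base outside alleles "
                f"{marker.allele_pair[0]}/{marker.allele_pair[1]}"
            )
    x, y = parts
    return (x, y) if x <= y else (y, x)


def save_panel(panel: GenotypePanel, path) -> None:
    membership = {}
    for mid in panel.id_set:
        membership[mid] = "id"
    for mid in panel.validation_set:
        membership[mid] = "validation"
    for mid in panel.confirmation_set:
        membership[mid] = "confirmation"
    lines = []
    for m in panel.markers:
        tag = membership.get(m.marker_id, "none")
        a, b = m.allele_pair
        lines.append(f"#marker\t{m.marker_id}\t{a}/{b}\t{tag}")
    header = ["genotype_id", "class", "parent1", "parent2"] + panel.marker_ids
    lines.append("\t".join(header))
    for g in panel.genotypes:
        row = [
            g.genotype_id,
            g.genotype_class,
            g.parent1 or "NA",
            g.parent2 or "NA",
        ] + [_format_call(g.call(mid)) for mid in panel.marker_ids]
        lines.append("\t".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def load_panel(path) -> GenotypePanel:
    markers: list = []
    sets: dict = {"id_set": [], "validation_set": [], "confirmation_set": []}
    genotypes: list = []
    header: Optional[list] = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#marker\t"):
                parts = line.split("\t")
                if len(parts) != 4:
                    raise PanelError(f"line {lineno}: malformed #marker line")
                _, mid, alleles, tag = parts
                bases = alleles.split("/")
                if len(bases) != 2:
                    raise PanelError(
                        f"line {lineno}: malformed alleles {alleles!r} for {mid}"
                    )
                markers.append(SNPMarker(mid, frozenset(bases)))
                if tag not in _SET_TAGS:
                    raise PanelError(f"line {lineno}: unknown set tag {tag!r}")
                key = _SET_TAGS[tag]
                if key:
                    sets[key].append(mid)
                continue
            if line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                if header[:4] != ["genotype_id", "class", "parent1", "parent2"]:
                    raise PanelError(f"line {lineno}: unexpected header {header[:4]}")
                marker_ids = header[4:]
                known = {m.marker_id for m in markers}
                for mid in marker_ids:
                    if mid not in known:
                        raise PanelError(
                            f"line {lineno}: column {mid!r} lacks a #marker "
                            "declaration"
                        )
                continue
            if len(cells) != len(header):
                raise PanelError(
                    f"line {lineno}: expected {len(header)} fields, got {len(cells)}"
                )
            gid, cls, p1, p2 = cells[:4]
            if any(g.genotype_id == gid for g in genotypes):
                raise PanelError(f"line {lineno}: duplicate genotype_id {gid!r}")
            calls = {}
            for mid, text in zip(header[4:], cells[4:]):
                marker = next(m for m in markers if m.marker_id == mid)
                calls[mid] = _parse_call(text, marker, lineno)
            genotypes.append(
                GenotypeRecord(
                    genotype_id=gid,
                    genotype_class=cls,
                    parent1=None if p1 == "NA" else p1,
                    parent2=None if p2 == "NA" else p2,
                    calls=calls,
                )
            )
    if header is None:
        raise PanelError("panel file has no genotype table")
    panel = GenotypePanel(markers=markers, genotypes=genotypes, **sets)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# Synthetic panel construction
# ---------------------------------------------------------------------------

_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]


def synthetic_panel(
    genotype_ids: Optional[Sequence[str]] = None,
    n_f1: int = 0,
    n_confirmation: int = 2,
) -> GenotypePanel:
    """Deterministic panel for a polycross of (by default) eight genotypes.

    Each genotype receives a distinct binary code over two banks of four
    homozygous markers (the second bank reverses bit order so both banks are
    distinguishing); id and validation sets are then chosen by the selection
    operators themselves. The last ``n_f1`` genotypes are marked as F1
    hybrids: heterozygous at the confirmation markers, homozygous elsewhere,
    with synthetic parent ids outside the panel.
    """
    if genotype_ids is None:
        genotype_ids = [f"G{i + 1}" for i in range(8)]
    genotype_ids = list(genotype_ids)
    n = len(genotype_ids)
    n_bits = max(1, (n - 1).bit_length())
    bank_a = [f"A{j + 1}" for j in range(n_bits + 1)]  # bits + parity
    bank_b = [f"B{j + 1}" for j in range(n_bits + 1)]
    conf = [f"C{j + 1}" for j in range(n_confirmation)]
    all_ids = bank_a + bank_b + conf
    markers = [
        SNPMarker(mid, frozenset(_ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]))
        for i, mid in enumerate(all_ids)
    ]
    by_id = {m.marker_id: m for m in markers}

    def homo(mid: str, bit: int) -> tuple:
        base = by_id[mid].allele_pair[bit]
        return (base, base)

    genotypes = []
    for i, gid in enumerate(genotype_ids):
        bits = [(i >> j) & 1 for j in range(n_bits)]
        parity = sum(bits) % 2
        code_a = bits + [parity]
        code_b = bits[::-1] + [1 - parity]
        calls = {}
        for mid, bit in zip(bank_a, code_a):
            calls[mid] = homo(mid, bit)
        for mid, bit in zip(bank_b, code_b):
            calls[mid] = homo(mid, bit)
        is_f1 = i >= n - n_f1
        for mid in conf:
            if is_f1:
                calls[mid] = by_id[mid].allele_pair
            else:
                calls[mid] = homo(mid, i % 2)
        genotypes.append(
            GenotypeRecord(
                genotype_id=gid,
                genotype_class="F1" if is_f1 else "inbred",
                parent1=f"{gid}.p1" if is_f1 else None,
                parent2=f"{gid}.p2" if is_f1 else None,
                calls=calls,
            )
        )
    panel = GenotypePanel(markers=markers, genotypes=genotypes)
    panel.id_set = minimal_distinguishing_set(panel)
    panel.validation_set = select_validation_set(panel, panel.id_set, k=4)
    panel.confirmation_set = conf
    panel.validate()
    return panel
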