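"""Domain types for the provirus construct, guide geometry and panel design rules.

Coordinates are 0-based, half-open throughout.  A guide's ``cut_position`` is
the index of the first base of the right-hand fragment produced by the blunt
double-strand break (the cut falls between ``cut_position - 1`` and
``cut_position``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from lvis._util import check_dna, revcomp

Arm = Literal["left", "right"]

PROTOSPACER_LEN = 20
#: SpCas9 blunt cut sits 3 bp on the protospacer (5') side of the PAM.
CUT_OFFSET_FROM_PAM = 3
PAM_LEN = 3


@dataclass(frozen=True)
class GuideSite:
    """One SpCas9 guide annotated on the construct.

    ``pam_position`` is the construct coordinate of the first PAM base (the
    "N" of NGG on the plus strand; the first "C" of the plus-strand CCN for a
    minus-strand guide).
    """

    protospacer: str
    strand: Literal["+", "-"]
    pam_position: int
    cut_position: int
    arm: Optional[Arm] = None
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"protospacer must be {PROTOSPACER_LEN} nt, got "
                f"{len(self.protospacer)} ({self.protospacer!r})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def pam_side(self) -> Arm:
        """Which cut fragment carries the PAM: 'left' or 'right'."""
        return "right" if self.pam_position >= self.cut_position else "left"


@dataclass
class ProvirusConstruct:
    """Integrated (proviral, SIN-LTR layout) vector genome plus its guides.

    The left terminus is coordinate 0 and the right terminus is
    ``len(sequence)``; arm lengths are measured from a guide's cut to the
    terminus it serves.
    """

    name: str
    sequence: str
    guides: list[GuideSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        check_dna(self.sequence, what=f"construct {self.name!r}")
        for g in self.guides:
            if not (0 <= g.cut_position <= len(self.sequence)):
                raise ValueError(
                    f"guide {g.name!r} cut_position {g.cut_position} outside "
                    f"construct [0, {len(self.sequence)}]"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def left_terminus(self) -> int:
        return 0

    @property
    def right_terminus(self) -> int:
        return self.length


@dataclass(frozen=True)
class ArmSpec:
    """Geometry of one guide's arm: cut-to-served-terminus segment."""

    arm: Arm
    cut_position: int
    arm_length: int
    outward_direction: Literal["toward_left_terminus", "toward_right_terminus"]
    guide_name: str = ""


@dataclass(frozen=True)
class Violation:
    """One broken panel-design rule."""

    rule: str
    guide: Optional[str]
    message: str


def scan_pam_sites(sequence: str) -> list[GuideSite]:
    """Enumerate every candidate SpCas9 guide on both strands.

    A plus-strand NGG PAM at ``[i, i+3)`` yields protospacer ``[i-20, i)``
    with the cut at ``i - 3``; a minus-strand guide (plus-strand CCN at
    ``[i, i+3)``) has its protospacer on ``[i+3, i+23)`` and cuts at
    ``i + 6``.  Candidates whose protospacer would fall outside the sequence
    or contains N are dropped.  Result is sorted by cut position.
    """
    check_dna(sequence)
    n = len(sequence)
    out: list[GuideSite] = []
    for i in range(n - 2):
        if sequence[i + 1 : i + 3] == "GG" and i >= PROTOSPACER_LEN:
            proto = sequence[i - PROTOSPACER_LEN : i]
            if "N" not in proto:
                out.append(
                    GuideSite(
                        protospacer=proto,
                        strand="+",
                        pam_position=i,
                        cut_position=i - CUT_OFFSET_FROM_PAM,
                    )
                )
        if sequence[i : i + 2] == "CC" and i + PAM_LEN + PROTOSPACER_LEN <= n:
            proto = revcomp(sequence[i + PAM_LEN : i + PAM_LEN + PROTOSPACER_LEN])
            if "N" not in proto:
                out.append(
                    GuideSite(
                        protospacer=proto,
                        strand="-",
                        pam_position=i,
                        cut_position=i + PAM_LEN + CUT_OFFSET_FROM_PAM,
                    )
                )
    out.sort(key=lambda g: (g.cut_position, g.strand))
    return out


def validate_guide_set(
    construct: ProvirusConstruct,
    min_junction_distance: int = 500,
    min_pair_spacing: int = 50,
) -> list[Violation]:
    """Check the enrichment panel against the design rules.

    R1  at least two guides per arm (cleavage redundancy);
    R2  every cut at least ``min_junction_distance`` from its served terminus;
    R3  cuts within an arm separated by at least ``min_pair_spacing``;
    R4  the A-tailable (PAM-side) cut fragment must contain the served
        terminus, so sequencing runs outward through the terminus into host;
    R5  left-arm and right-arm guides sit on opposite strands.

    Returns the full list of violations; an empty list means the panel is
    valid.
    """
    if not construct.guides:
        raise ValueError("construct has no guides")
    for g in construct.guides:
        if not (0 <= g.cut_position <= construct.length):
            raise ValueError(f"guide {g.name!r} outside construct")
        if g.arm not in ("left", "right"):
            raise ValueError(f"guide {g.name!r} has no arm assignment")

    violations: list[Violation] = []
    by_arm: dict[Arm, list[GuideSite]] = {"left": [], "right": []}
    for g in construct.guides:
        by_arm[g.arm].append(g)

    for arm, guides in by_arm.items():
        if len(guides) < 2:
            violations.append(
                Violation(
                    "R1",
                    None,
                    f"{arm} arm has {len(guides)} guide(s); >=2 required for "
                    "cleavage redundancy",
                )
            )
        for g in guides:
            dist = g.cut_position if arm == "left" else construct.length - g.cut_position
            if dist < min_junction_distance:
                violations.append(
                    Violation(
                        "R2",
                        g.name,
                        f"cut {dist} bp from {arm} terminus; minimum distance "
                        f"from the integration junction is {min_junction_distance}",
                    )
                )
            served_side: Arm = "left" if arm == "left" else "right"
            if g.pam_side != served_side:
                violations.append(
                    Violation(
                        "R4",
                        g.name,
                        f"PAM-side (A-tailable) fragment is the {g.pam_side} "
                        f"fragment but the served terminus lies in the "
                        f"{served_side} fragment; outward sequencing impossible",
                    )
                )
        guides_sorted = sorted(guides, key=lambda g: g.cut_position)
        for a, b in zip(guides_sorted, guides_sorted[1:]):
            if b.cut_position - a.cut_position < min_pair_spacing:
                violations.append(
                    Violation(
                        "R3",
                        b.name,
                        f"cuts {a.cut_position} and {b.cut_position} only "
                        f"{b.cut_position - a.cut_position} bp apart; minimum "
                        f"spacing {min_pair_spacing}",
                    )
                )
    left_strands = {g.strand for g in by_arm["left"]}
    right_strands = {g.strand for g in by_arm["right"]}
    if left_strands & right_strands:
        violations.append(
            Violation(
                "R5",
                None,
                "left-arm and right-arm guides must sit on opposite strands "
                f"(left: {sorted(left_strands)}, right: {sorted(right_strands)})",
            )
        )
    return violations


def arm_specs(construct: ProvirusConstruct) -> list[ArmSpec]:
    """One :class:`ArmSpec` per guide.

    The minimum ``arm_length`` over an arm's specs defines that arm's
    size-selection threshold downstream.
    """
    specs: list[ArmSpec] = []
    for g in construct.guides:
        if g.arm == "left":
            length = g.cut_position
            direction = "toward_left_terminus"
        elif g.arm == "right":
            length = construct.length - g.cut_position
            direction = "toward_right_terminus"
        else:
            raise ValueError(f"guide {g.name!r} has no arm assignment")
        if length <= 0:
            raise ValueError(f"guide {g.name!r} has non-positive arm length")
        specs.append(
            ArmSpec(
                arm=g.arm,
                cut_position=g.cut_position,
                arm_length=length,
                outward_direction=direction,
                guide_name=g.name,
            )
        )
    return specs


def design_guides(
    sequence: str,
    n_per_arm: int = 2,
    min_junction_distance: int = 500,
    max_junction_distance: int = 1500,
    min_pair_spacing: int = 50,
) -> list[GuideSite]:
    """Pick a rule-compliant panel of guides from the candidate scan.

    Left-arm guides must be minus-strand and right-arm guides plus-strand so
    that the PAM-side fragment contains the served terminus (rule R4).
    Raises ValueError when the sequence offers too few compliant candidates.
    """
    candidates = scan_pam_sites(sequence)
    n = len(sequence)

    def pick(cands: Iterable[GuideSite], arm: Arm) -> list[GuideSite]:
        chosen: list[GuideSite] = []
        for c in sorted(cands, key=lambda g: g.cut_position):
            if chosen and c.cut_position - chosen[-1].cut_position < min_pair_spacing:
                continue
            chosen.append(c)
            if len(chosen) == n_per_arm:
                break
        if len(chosen) < n_per_arm:
            raise ValueError(
                f"could not place {n_per_arm} compliant guides on the {arm} arm"
            )
        return [
            replace(c, arm=arm, name=f"{arm}_{i + 1}") for i, c in enumerate(chosen)
        ]

    left = pick(
        (
            c
            for c in candidates
            if c.strand == "-"
            and min_junction_distance <= c.cut_position <= max_junction_distance
        ),
        "left",
    )
    right = pick(
        (
            c
            for c in candidates
            if c.strand == "+"
            and min_junction_distance <= n - c.cut_position <= max_junction_distance
        ),
        "right",
    )
    return left + right


def count_offtargets(protospacer: str, genome: dict[str, str], max_mismatch: int = 1) -> int:
    """Count exact and near-exact (<= ``max_mismatch`` substitutions, NGG-adjacent)
    occurrences of a protospacer in a genome; no cutoff is asserted here."""
    if max_mismatch > 1:
        raise ValueError("only exact or 1-mismatch counting supported")
    hits = 0
    targets = [protospacer, revcomp(protospacer)]
    for seq in genome.values():
        for t, minus in ((targets[0], False), (targets[1], True)):
            for i in range(len(seq) - len(t) - 2):
                window = seq[i : i + len(t)]
                mism = sum(a != b for a, b in zip(window, t))
                if mism > max_mismatch:
                    continue
                pam = seq[i + len(t) + 1 : i + len(t) + 3] if not minus else None
                if minus:
                    pam_ok = seq[i - 3 : i - 1] == "CC" if i >= 3 else False
                else:
                    pam_ok = pam == "GG"
                if pam_ok:
                    hits += 1
    return hits


def write_construct(construct: ProvirusConstruct, fasta_path, guides_path) -> None:
    """Write sequence as FASTA plus a TSV sidecar with the guide table."""
    record = SeqRecord(Seq(construct.sequence), id=construct.name, description="")
    SeqIO.write([record], str(fasta_path), "fasta")
    with open(guides_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["name", "protospacer", "strand", "pam_position", "cut_position", "arm"]
        )
        for g in construct.guides:
            writer.writerow(
                [g.name, g.protospacer, g.strand, g.pam_position, g.cut_position, g.arm]
            )


def load_construct(fasta_path, guides_path=None) -> ProvirusConstruct:
    """Load a construct FASTA and optional guide-table TSV sidecar."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one construct sequence, got {len(records)}")
    rec = records[0]
    guides: list[GuideSite] = []
    if guides_path is not None:
        with open(guides_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                guides.append(
                    GuideSite(
                        name=row["name"],
                        protospacer=row["protospacer"],
                        strand=row["strand"],
                        pam_position=int(row["pam_position"]),
                        cut_position=int(row["cut_position"]),
                        arm=row["arm"] or None,
                    )
                )
    return ProvirusConstruct(name=rec.id, sequence=str(rec.seq).upper(), guides=guides)
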