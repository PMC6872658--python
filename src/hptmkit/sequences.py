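"""Histone variant sequences, mature-residue coordinates and variant calling.

Histone nomenclature numbers residues on the *mature* protein, i.e. after
removal of the initiator methionine: H3K27 is lysine 27 of the Met-stripped
chain.  Sequence variants of one family (e.g. H3.1/H3.2 vs H3.3) differ at a
handful of positions; a bottom-up peptide can be assigned to a variant only
when one of those distinguishing positions falls inside the peptide.  When it
does not, the peptide is reported at the family level ("H3").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "HistoneVariant",
    "VariantGroup",
    "load_histone_fasta",
    "packaged_fasta_path",
    "load_packaged_variants",
    "distinguishing_positions",
    "variant_group_for_peptide",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_HEADER_RE = re.compile(r"^(?P<name>[A-Za-z0-9.\-]+)\|(?P<family>[A-Za-z0-9]+)\|(?P<acc>\S*)$")


@dataclass(frozen=True, order=True)
class HistoneVariant:
    """A mature histone sequence with variant identity.

    ``sequence`` is the Met-stripped chain, so index ``pos - 1`` is mature
    residue ``pos`` (H3 position 27 is K in every packaged H3 variant).
    """

    name: str
    family: str
    sequence: str
    source_accession: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"variant {self.name}: non-canonical residue letters {sorted(bad)}"
            )

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based mature position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantGroup:
    """A set of indistinguishable variants with its rendered label.

    The label is deterministic: member names sorted and joined with "/",
    collapsing to the bare family name when the group covers every variant of
    the family (the "no variant could be called" case).
    """

    members: frozenset[str]
    family: str
    label: str = field(compare=False, default="")

    @classmethod
    def build(
        cls,
        members: Iterable[str],
        family: str,
        family_members: Iterable[str] | None = None,
    ) -> "VariantGroup":
        mem = frozenset(members)
        if not mem:
            raise ValueError("a variant group needs at least one member")
        if family_members is not None and mem == frozenset(family_members):
            label = family
        else:
            label = "/".join(sorted(mem))
        return cls(members=mem, family=family, label=label)


def load_histone_fasta(path, strip_init_met: bool = True) -> set[HistoneVariant]:
    """Read histone variants from a FASTA with ``>NAME|FAMILY|ACCESSION`` headers.

    The initiator Met is stripped when the raw record starts with M and
    ``strip_init_met`` is true (the default), yielding mature numbering.

    Raises
    ------
    ValueError
        On malformed headers/records (naming the offending line) or on
        duplicate variant names.
    """
    variants: dict[str, HistoneVariant] = {}
    n = 0
    with open(path) as handle:
        # Light structural check so errors can name a line; Bio.SeqIO is
        # lenient about text before the first header.
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            n += 1
            m = _HEADER_RE.match(record.description)
            if not m:
                raise ValueError(
                    f"{path}: record {n}: header {record.description!r} does not match "
                    "'NAME|FAMILY|ACCESSION'"
                )
            seq = str(record.seq).upper()
            if strip_init_met and seq.startswith("M"):
                seq = seq[1:]
            name = m.group("name")
            if name in variants:
                raise ValueError(f"{path}: duplicate variant name {name!r}")
            variants[name] = HistoneVariant(
                name=name,
                family=m.group("family"),
                sequence=seq,
                source_accession=m.group("acc"),
            )
    if n == 0:
        logger.warning("%s: empty FASTA, no variants loaded", path)
    return set(variants.values())


def packaged_fasta_path(family: str):
    """Path-like handle to a packaged histone FASTA ('h3', 'h4' or 'h2a')."""
    name = f"histone_{family.lower()}.fasta"
    ref = resources.files("hptmkit.data") / name
    if not ref.is_file():
        raise FileNotFoundError(f"no packaged FASTA for family {family!r}")
    return ref


def load_packaged_variants(family: str) -> set[HistoneVariant]:
    """Load the packaged variant set for one family ('h3', 'h4', 'h2a')."""
    ref = packaged_fasta_path(family)
    with resources.as_file(ref) as p:
        return load_histone_fasta(p)


def distinguishing_positions(
    variants: Iterable[HistoneVariant],
) -> dict[int, dict[str, frozenset[str]]]:
    """Mature positions where at least two variants differ.

    Returns ``{position: {residue_letter: frozenset(variant_names)}}``, i.e.
    the partition of the variant set by residue letter at each discriminating
    column.  Variants of unequal length are compared on the shared prefix
    (positions up to the shortest sequence).  Fewer than two distinct
    variants yield an empty map.
    """
    vs = sorted(set(variants))
    if len(vs) < 2:
        return {}
    families = {v.family for v in vs}
    if len(families) > 1:
        raise ValueError(f"variants span multiple families: {sorted(families)}")
    limit = min(len(v) for v in vs)
    out: dict[int, dict[str, frozenset[str]]] = {}
    for pos in range(1, limit + 1):
        by_letter: dict[str, set[str]] = {}
        for v in vs:
            by_letter.setdefault(v.residue(pos), set()).add(v.name)
        if len(by_letter) > 1:
            out[pos] = {aa: frozenset(names) for aa, names in by_letter.items()}
    return out


def variant_group_for_peptide(
    span: tuple[int, int],
    observed_residues: Mapping[int, str],
    variants: Iterable[HistoneVariant],
) -> VariantGroup:
    """Call the variant group consistent with a peptide's observed residues.

    ``span`` is a 1-based inclusive (start, end) on mature coordinates.
    ``observed_residues`` maps each distinguishing position inside the span to
    the residue letter actually observed on the peptide.  A span covering no
    distinguishing position yields the full family group labelled with the
    family name.  Enlarging the span can only shrink (never grow) the group.

    Raises
    ------
    ValueError
        If the observations are inconsistent with every variant, or if a
        distinguishing position in the span is not covered by
        ``observed_residues``.
    """
    vs = sorted(set(variants))
    if not vs:
        raise ValueError("empty variant set")
    family = vs[0].family
    start, end = span
    if start < 1 or end < start:
        raise ValueError(f"invalid span {span}")
    dpos = distinguishing_positions(vs)
    relevant = [p for p in dpos if start <= p <= end]
    consistent = {v.name for v in vs}
    for p in relevant:
        if p not in observed_residues:
            raise ValueError(f"distinguishing position {p} in span {span} not observed")
        letter = observed_residues[p]
        part = dpos[p].get(letter)
        if part is None:
            raise ValueError(
                f"residue {letter!r} at position {p} matches no variant in the family"
            )
        consistent &= part
    if not consistent:
        raise ValueError(
            f"observed residues {dict(observed_residues)} inconsistent with every variant"
        )
    return VariantGroup.build(consistent, family, family_members=[v.name for v in vs])
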