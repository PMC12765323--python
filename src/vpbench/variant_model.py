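"""Protein-level variant identity: substitutions, keys, and cross-source matching.

Variants are matched across the score, clinical, and population sources at the
protein level only — gene symbol plus amino-acid substitution. Genomic
coordinates, when present, ride along as annotation and never participate in
joins: predictor scores are reported for a single representative transcript
per gene, while clinical submissions may cite other isoforms, so the protein
change is the one identity all sources share.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Data.IUPACData import protein_letters, protein_letters_1to3, protein_letters_3to1

logger = logging.getLogger(__name__)

#: The 20 canonical one-letter amino acid codes. Selenocysteine (U) and
#: pyrrolysine (O) are outside the predictor's substitution space and rejected.
CANONICAL_AA: frozenset[str] = frozenset(protein_letters)

_THREE_TO_ONE = {
    three.capitalize(): one
    for three, one in protein_letters_3to1.items()
    if one in CANONICAL_AA
}
_ONE_TO_THREE = {one: three for three, one in _THREE_TO_ONE.items()}
assert len(_THREE_TO_ONE) == 20

_AA3_ALT = "|".join(_THREE_TO_ONE)
_RE_THREE = re.compile(
    rf"^(?:p\.)?(?P<ref>{_AA3_ALT})(?P<pos>[0-9]+)(?P<alt>{_AA3_ALT})$", re.IGNORECASE
)
_RE_ONE = re.compile(r"^(?:p\.)?(?P<ref>[A-Za-z])(?P<pos>[0-9]+)(?P<alt>[A-Za-z])$")
# Tokens that mark a well-formed HGVS change as something other than a simple
# missense substitution (stop gain, frameshift, indel, synonymous, extension).
_RE_NON_MISSENSE = re.compile(r"(ter|fs|del|dup|ins|ext)|\*|=", re.IGNORECASE)


class ProteinChangeError(ValueError):
    """Base class for protein-change parsing failures."""


class ParseError(ProteinChangeError):
    """The string is not a recognizable protein substitution."""


class NotMissenseError(ProteinChangeError):
    """The string is valid HGVS but not a missense substitution."""


@dataclass(frozen=True, order=True)
class ProteinSubstitution:
    """A single amino-acid substitution at a 1-based residue position."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in CANONICAL_AA or self.alt_aa not in CANONICAL_AA:
            raise ParseError(
                f"amino acid codes must be canonical one-letter symbols, "
                f"got {self.ref_aa!r}>{self.alt_aa!r}"
            )
        if self.ref_aa == self.alt_aa:
            raise NotMissenseError(
                f"{self.ref_aa}{self.position}{self.alt_aa} is synonymous, "
                "not a missense substitution"
            )
        if self.position < 1:
            raise ParseError(f"residue position must be >= 1, got {self.position}")

    def short(self) -> str:
        """One-letter shorthand, e.g. ``G1961E``."""
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    def hgvs(self) -> str:
        """Three-letter HGVS protein notation, e.g. ``p.Gly1961Glu``."""
        return f"p.{_ONE_TO_THREE[self.ref_aa]}{self.position}{_ONE_TO_THREE[self.alt_aa]}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.short()


def parse_protein_change(text: str) -> ProteinSubstitution:
    """Parse an HGVS or shorthand protein change into a substitution.

    Accepts three-letter HGVS with or without the ``p.`` prefix
    (``p.Gly1961Glu``, ``Asn1868Ile``) and one-letter shorthand (``G12D``).

    Raises
    ------
    NotMissenseError
        For well-formed changes that are not missense substitutions: stop
        gains (``Ter``/``*``), frameshifts, deletions/duplications/insertions,
        and synonymous changes (ref == alt).
    ParseError
        For anything else that cannot be read as a substitution.
    """
    if not text or not text.strip():
        raise ParseError("empty protein change")
    text = text.strip()
    m = _RE_THREE.match(text)
    if m:
        return ProteinSubstitution(
            _THREE_TO_ONE[m.group("ref").capitalize()],
            int(m.group("pos")),
            _THREE_TO_ONE[m.group("alt").capitalize()],
        )
    if _RE_NON_MISSENSE.search(text):
        raise NotMissenseError(f"{text!r} is not a missense substitution")
    m = _RE_ONE.match(text)
    if m:
        ref, alt = m.group("ref").upper(), m.group("alt").upper()
        if ref not in CANONICAL_AA or alt not in CANONICAL_AA:
            raise ParseError(f"{text!r} uses a non-canonical amino acid code")
        return ProteinSubstitution(ref, int(m.group("pos")), alt)
    raise ParseError(f"cannot parse protein change {text!r}")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Join key for a variant: uppercase gene symbol + protein substitution.

    Gene comparison is case-insensitive (symbols are normalized to uppercase
    at construction); substitution comparison is exact.
    """

    gene: str
    substitution: ProteinSubstitution

    def __post_init__(self) -> None:
        gene = self.gene.strip().upper()
        if not gene:
            raise ValueError("gene symbol must be non-empty")
        object.__setattr__(self, "gene", gene)

    def __str__(self) -> str:
        return f"{self.gene}:{self.substitution.short()}"


def make_key(gene: str, change: str) -> VariantKey:
    """Build a :class:`VariantKey` from a gene symbol and a protein change string."""
    return VariantKey(gene, parse_protein_change(change))


@dataclass(frozen=True)
class MatchReport:
    """Accounting of a predictor/clinical key join.

    ``matched + unmatched_clinical`` equals the number of clinical keys
    offered; ``reconciled_by_override`` counts matches achieved through the
    override map rather than the exact join.
    """

    matched: int
    unmatched_predictor: int
    unmatched_clinical: int
    reconciled_by_override: int = 0

    def __post_init__(self) -> None:
        for name in ("matched", "unmatched_predictor", "unmatched_clinical",
                     "reconciled_by_override"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def match_records(
    predictor_keys: Iterable[VariantKey],
    clinical_keys: Iterable[VariantKey],
    overrides: Mapping[VariantKey, VariantKey] | None = None,
) -> tuple[list[tuple[VariantKey, VariantKey]], MatchReport]:
    """Join clinical keys against predictor keys, with manual-style overrides.

    The join is exact on the key. Clinical keys left unmatched are then looked
    up in ``overrides`` (clinical key -> predictor key), the machine analogue
    of manually reconciling transcript-versioning and isoform discrepancies.
    An override pointing at a predictor key that does not exist is warned
    about and the clinical key counted unmatched.

    Returns
    -------
    (pairs, report)
        ``pairs`` is a list of ``(clinical_key, predictor_key)`` tuples in
        deterministic (sorted) order; ``report`` accounts for every input key.
    """
    overrides = dict(overrides or {})
    predictor = set(predictor_keys)
    clinical = set(clinical_keys)

    pairs: list[tuple[VariantKey, VariantKey]] = []
    reconciled = 0
    unmatched_clinical = 0
    for ck in sorted(clinical):
        if ck in predictor:
            pairs.append((ck, ck))
        elif ck in overrides and overrides[ck] in predictor:
            pairs.append((ck, overrides[ck]))
            reconciled += 1
        else:
            if ck in overrides:
                logger.warning(
                    "override target %s for clinical key %s absent from "
                    "predictor set; counted unmatched", overrides[ck], ck,
                )
            unmatched_clinical += 1

    matched_predictor = {pk for _, pk in pairs}
    report = MatchReport(
        matched=len(pairs),
        unmatched_predictor=len(predictor - matched_predictor),
        unmatched_clinical=unmatched_clinical,
        reconciled_by_override=reconciled,
    )
    return pairs, report
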