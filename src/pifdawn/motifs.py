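"""Strand-aware IUPAC motif scanning and hypergeometric set enrichment.

A gene "contains" a motif if its promoter window has at least one match
on either strand; enrichment of motif-containing genes in a gene set
versus the array background is scored with the upper tail of the
hypergeometric distribution, mirroring the classical promoter-element
over-representation test.  The same machinery serves generic category
enrichment for user-supplied annotation maps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .core import PipelineError

#: IUPAC nucleotide codes -> the concrete bases they stand for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

#: The four elements tested in the dawn-transcriptome promoter analysis:
#: the G-box and the PIF-binding element (PBE/HUD), both E-box variants
#: bound by PIF bHLH factors, the extended G-box/PBE element, and the
#: ABA-responsive element.
DEFAULT_MOTIFS: dict[str, str] = {
    "GBOX": "CACGTG",
    "PBE": "CACATG",
    "EXT": "CACRTGGG",
    "ABRE": "ACGTGGC",
}


@dataclass(frozen=True)
class MotifDefinition:
    """A named IUPAC motif; lowercase input is normalized to uppercase."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "iupac", self.iupac.upper())
        if not self.iupac:
            raise PipelineError(f"motif {self.name!r}: empty pattern")
        for letter in self.iupac:
            if letter not in IUPAC_CODES:
                raise PipelineError(
                    f"motif {self.name!r}: invalid IUPAC letter {letter!r}"
                )

    def reverse_complement(self) -> str:
        return "".join(_COMPLEMENT[c] for c in reversed(self.iupac))

    @property
    def is_palindromic(self) -> bool:
        return self.reverse_complement() == self.iupac


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise PipelineError(f"invalid nucleotide letter {exc.args[0]!r}") from exc


def _pattern(iupac: str) -> re.Pattern:
    # Motif N matches any base including an N in the sequence; every
    # other code matches only its concrete bases, so sequence Ns never
    # satisfy a non-N motif position.
    parts = []
    for letter in iupac:
        opts = IUPAC_CODES[letter]
        if letter == "N":
            opts += "N"
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping matches are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def scan_motif(sequence: str, motif: MotifDefinition) -> list[tuple[int, str]]:
    """All match start offsets of a motif in a sequence, both strands.

    Returns ``(offset, strand)`` pairs with 0-based offsets on the given
    sequence; ``strand`` is ``'+'`` for the motif itself and ``'-'`` for
    its reverse complement.  Overlapping matches are all reported.  For
    palindromic motifs the minus-strand duplicate at the same locus is
    collapsed to the single plus-strand site.
    """
    if not sequence:
        raise PipelineError("cannot scan an empty sequence")
    seq = sequence.upper()
    hits = [(m.start(), "+") for m in _pattern(motif.iupac).finditer(seq)]
    if not motif.is_palindromic:
        rc = _pattern(motif.reverse_complement())
        hits += [(m.start(), "-") for m in rc.finditer(seq)]
    return sorted(hits)


def genes_with_motif(
    promoters: Mapping[str, str], motif: MotifDefinition
) -> set[str]:
    """Genes whose promoter has >= 1 match on either strand."""
    fwd = _pattern(motif.iupac)
    pats = [fwd]
    if not motif.is_palindromic:
        pats.append(_pattern(motif.reverse_complement()))
    return {
        gid
        for gid, seq in promoters.items()
        if any(p.search(seq.upper()) for p in pats)
    }


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k = set genes with the feature, n = set size, K = background genes
    with the feature, N = background size.
    """
    if not (0 <= k <= min(n, K) and k <= n <= N and 0 <= K <= N):
        raise PipelineError(
            f"hypergeometric bounds violated: k={k}, n={n}, K={K}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    """One motif's (or category's) enrichment in a gene set."""

    name: str
    k: int
    n: int
    K: int
    N: int
    fraction_in_set: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def _enrich_one(
    name: str, members: set[str], gene_set: set[str], background: set[str]
) -> EnrichmentResult:
    k = len(gene_set & members)
    n = len(gene_set)
    K = len(background & members)
    N = len(background)
    return EnrichmentResult(
        name=name,
        k=k,
        n=n,
        K=K,
        N=N,
        fraction_in_set=k / n if n else float("nan"),
        p_value=hypergeom_enrichment(k, n, K, N),
    )


def enrich_gene_set(
    promoters: Mapping[str, str],
    motifs: Sequence[MotifDefinition],
    gene_set: Iterable[str],
    background: Iterable[str],
    composites: Mapping[str, Sequence[str]] | None = None,
    composite_mode: str = "any",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each motif in a gene set vs background.

    ``composites`` maps a composite name (e.g. ``"GBOX+PBE"``) to motif
    names; with ``composite_mode="any"`` a gene counts if it contains
    any of them (presence of either element), with ``"all"`` it must
    contain every one (co-occurrence).
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise PipelineError("gene_set must be a subset of the background")
    missing = sorted(background - set(promoters))[:10]
    if missing:
        raise PipelineError(f"genes without promoter sequence: {missing}")
    if composite_mode not in ("any", "all"):
        raise PipelineError(f"unknown composite_mode {composite_mode!r}")

    by_name = {m.name: genes_with_motif(promoters, m) for m in motifs}
    results = [
        _enrich_one(m.name, by_name[m.name], gene_set, background) for m in motifs
    ]
    for comp_name, parts in (composites or {}).items():
        sets = [by_name[p] for p in parts]
        members = set.union(*sets) if composite_mode == "any" else set.intersection(*sets)
        results.append(_enrich_one(comp_name, members, gene_set, background))
    return results


def category_enrichment(
    annotation: Mapping[str, Iterable[str]],
    gene_set: Iterable[str],
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each annotation category in a gene set.

    ``annotation`` maps gene id -> iterable of category names; genes
    absent from the map carry no categories.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise PipelineError("gene_set must be a subset of the background")
    members: dict[str, set[str]] = {}
    for gid, cats in annotation.items():
        for cat in cats:
            members.setdefault(cat, set())
            if gid in background:
                members[cat].add(gid)
    return [
        _enrich_one(cat, genes, gene_set, background)
        for cat, genes in sorted(members.items())
    ]


def default_motif_definitions() -> list[MotifDefinition]:
    return [MotifDefinition(name, iupac) for name, iupac in DEFAULT_MOTIFS.items()]
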