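"""Chromosome assignment from gene identifiers and knockout co-location.

Two systematic naming conventions are decoded directly:

* ``yali`` — Yarrowia lipolytica CLIB122 identifiers (``YALI0F17996g``):
  the sixth character is the chromosome letter A-F.
* ``sgd-systematic`` — budding-yeast ORF names (``YPR160W``): the second
  letter maps A..P onto the 16 chromosomes I..XVI, the third letter is the
  chromosome arm (L/R), and the trailing W/C letter is the Watson or Crick
  strand.

Anything else falls back to a custom gene->chromosome map when available;
otherwise the locus is reported as unknown rather than raising, so scoring
can count unplaceable genes explicitly.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .model import StrainDesign

__all__ = ["GeneLocus", "chromosome_of", "loci_for", "same_chromosome_score"]

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
]
_SGD_CHROMOSOME = {letter: _ROMAN[i] for i, letter in enumerate("ABCDEFGHIJKLMNOP")}

_YALI_RE = re.compile(r"^YALI0([A-F])\d+g$", re.IGNORECASE)
_SGD_RE = re.compile(r"^Y([A-P])([LR])\d{3}([WC])(?:-[A-Z])?$", re.IGNORECASE)


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str | None
    arm: str = "unknown"  # {"left", "right", "unknown"}
    strand: str = "unknown"  # {"Watson", "Crick", "unknown"}

    @property
    def known(self) -> bool:
        return self.chromosome is not None


def chromosome_of(
    gene_id: str,
    convention: str = "auto",
    custom_map: Mapping[str, str] | None = None,
) -> GeneLocus:
    """Resolve a gene identifier to its chromosome.

    ``convention`` is one of ``yali``, ``sgd-systematic``, ``custom-map`` or
    ``auto`` (try yali, then sgd, then the custom map).  Unresolvable
    identifiers give a locus with ``chromosome=None`` — not an exception —
    so downstream scoring can count them separately.
    """
    if not gene_id:
        raise ValueError("empty gene identifier")

    if convention in ("yali", "auto"):
        m = _YALI_RE.match(gene_id)
        if m:
            return GeneLocus(gene_id, m.group(1).upper())
        if convention == "yali":
            return _custom_or_unknown(gene_id, custom_map)
    if convention in ("sgd-systematic", "auto"):
        m = _SGD_RE.match(gene_id)
        if m:
            chrom_letter, arm_letter, strand_letter = (s.upper() for s in m.groups())
            return GeneLocus(
                gene_id,
                _SGD_CHROMOSOME[chrom_letter],
                arm="left" if arm_letter == "L" else "right",
                strand="Watson" if strand_letter == "W" else "Crick",
            )
        if convention == "sgd-systematic":
            return _custom_or_unknown(gene_id, custom_map)
    if convention in ("custom-map", "auto"):
        return _custom_or_unknown(gene_id, custom_map)
    raise ValueError(f"unknown naming convention {convention!r}")


def _custom_or_unknown(gene_id: str, custom_map: Mapping[str, str] | None) -> GeneLocus:
    if custom_map and gene_id in custom_map:
        return GeneLocus(gene_id, custom_map[gene_id])
    return GeneLocus(gene_id, None)


def loci_for(
    genes: Iterable[str],
    convention: str = "auto",
    custom_map: Mapping[str, str] | None = None,
) -> dict[str, GeneLocus]:
    return {g: chromosome_of(g, convention, custom_map) for g in genes}


def same_chromosome_score(
    design: StrainDesign, loci: Mapping[str, GeneLocus]
) -> float:
    """Fraction of a design's deletions sitting on the modal chromosome.

    Genes with unknown loci count in the denominator but can never form the
    modal group.  An empty deletion set scores 1 (vacuously co-located).
    """
    if not design.deletions:
        return 1.0
    chromosomes = [
        loci[g].chromosome
        for g in design.deletions
        if g in loci and loci[g].known
    ]
    if not chromosomes:
        return 0.0
    modal_count = Counter(chromosomes).most_common(1)[0][1]
    return modal_count / len(design.deletions)
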