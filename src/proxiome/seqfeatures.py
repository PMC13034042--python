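"""Sequence-level computations: charge/pI, mass, NLS scanning, amplicons.

* Net charge at a given pH via the Henderson-Hasselbalch sum over ionizable
  groups; the isoelectric point is found by bisection (charge is strictly
  decreasing in pH).  The default pKa set is the Bjellqvist set used by the
  common pI/MW services.
* Average molecular mass (sum of average residue masses plus one water).
* Motif scanners for the classical monopartite NLS consensus K-K/R-x-K/R and
  for the basic PY-NLS: a basic-enriched stretch followed by an
  R/K/H-x(2-5)-P-[Y/phi] signature (phi = hydrophobic), the signal class
  recognized by Kap104/Kapbeta2-type importins.
* In-silico PCR: exact-match amplicon prediction for a primer pair on a
  linear plus-strand template.

All coordinates are 1-based and inclusive, the residue-numbering convention
of the protein literature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

__all__ = [
    "PROTEIN_ALPHABET",
    "DNA_ALPHABET",
    "HYDROPHOBIC",
    "BJELLQVIST",
    "SequenceRecord",
    "PkaSet",
    "MotifHit",
    "PrimerPair",
    "Amplicon",
    "net_charge",
    "isoelectric_point",
    "molecular_weight",
    "scan_cnls",
    "scan_bpy_nls",
    "predict_amplicon",
    "read_fasta",
    "write_fasta",
    "fetch_uniprot_fasta",
]

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = set("ACGT")
#: Hydrophobic residues accepted at the last position of the PY-NLS
#: signature in addition to tyrosine.
HYDROPHOBIC = set("LIVFMW")
BASIC = set("KRH")
WATER_MASS = 18.0153  # Da, condensation water


@dataclass(frozen=True)
class SequenceRecord:
    """A validated protein or nucleotide sequence."""

    id: str
    residues: str
    kind: str = "protein"

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if not seq:
            raise ValueError(f"{self.id!r}: empty sequence")
        if self.kind == "protein":
            bad = set(seq) - PROTEIN_ALPHABET
        elif self.kind == "nucleotide":
            bad = set(seq) - DNA_ALPHABET
        else:
            raise ValueError(f"kind must be 'protein' or 'nucleotide', got {self.kind!r}")
        if bad:
            raise ValueError(f"{self.id!r}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PkaSet:
    """pKa values (and implicit charge signs) of the ionizable groups.

    Positive groups: free N-terminus, K, R, H.  Negative groups: free
    C-terminus, D, E, C, Y.  The default values are the Bjellqvist set.
    """

    n_terminus: float = 7.50
    c_terminus: float = 3.55
    D: float = 4.05
    E: float = 4.45
    C: float = 9.00
    Y: float = 10.00
    H: float = 5.98
    K: float = 10.00
    R: float = 12.00

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 < v < 14.0):
                raise ValueError(f"pKa {name}={v} outside (0, 14)")


BJELLQVIST = PkaSet()


def net_charge(seq: SequenceRecord | str, pH: float, pka: PkaSet = BJELLQVIST) -> float:
    """Henderson-Hasselbalch net charge at ``pH`` in elementary-charge units.

    Each positive group contributes ``1/(1+10**(pH-pKa))``; each negative
    group contributes ``-1/(1+10**(pKa-pH))``.
    """
    residues = _protein_residues(seq)
    pos = [pka.n_terminus]
    neg = [pka.c_terminus]
    side = {"K": pka.K, "R": pka.R, "H": pka.H}
    side_neg = {"D": pka.D, "E": pka.E, "C": pka.C, "Y": pka.Y}
    for aa in residues:
        if aa in side:
            pos.append(side[aa])
        elif aa in side_neg:
            neg.append(side_neg[aa])
    charge = sum(1.0 / (1.0 + 10.0 ** (pH - pk)) for pk in pos)
    charge -= sum(1.0 / (1.0 + 10.0 ** (pk - pH)) for pk in neg)
    return charge


def isoelectric_point(
    seq: SequenceRecord | str,
    pka: PkaSet = BJELLQVIST,
    charge_tol: float = 1e-6,
    ph_tol: float = 1e-4,
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    Iterates until ``|charge| < charge_tol`` or the bracketing interval is
    narrower than ``ph_tol``; deterministic.  Requires at least one positive
    and one negative ionizable group (free termini always provide both).
    """
    residues = _protein_residues(seq)
    # The free N- and C-termini always provide one positive and one negative
    # ionizable group, so the zero crossing exists and is unique (the charge
    # is strictly decreasing in pH).
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(residues, mid, pka)
        if abs(c) < charge_tol or (hi - lo) < ph_tol:
            return mid
        if c > 0:  # still positively charged, pI is at higher pH
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def molecular_weight(seq: SequenceRecord | str) -> float:
    """Average molecular mass in Da (residue masses + one water)."""
    residues = _protein_residues(seq)
    return float(_bio_molecular_weight(residues, seq_type="protein", monoisotopic=False))


def _protein_residues(seq: SequenceRecord | str) -> str:
    if isinstance(seq, SequenceRecord):
        if seq.kind != "protein":
            raise ValueError(f"{seq.id!r}: protein sequence required")
        return seq.residues
    rec = SequenceRecord("anonymous", str(seq), "protein")
    return rec.residues


# ---------------------------------------------------------------------------
# NLS scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    """A located NLS match; coordinates 1-based inclusive.

    For bPY-NLS hits, ``anchor_pos`` is the R/K/H anchor, ``py_pos`` the
    (P, Y/phi) position pair, ``n_basic`` the K/R/H count in the upstream
    window, and ``c_term_distance`` the residue count between the hit end and
    the C-terminus (0 = ends at the terminus).
    """

    kind: str  # "cNLS" | "bPY"
    start: int
    end: int
    match: str
    anchor_pos: int | None = None
    py_pos: tuple[int, int] | None = None
    n_basic: int | None = None
    c_term_distance: int | None = None

    @property
    def near_c_terminus(self) -> bool:
        """True when the signature ends within 3 residues of the C-terminus."""
        return self.c_term_distance is not None and self.c_term_distance <= 3


def scan_cnls(seq: SequenceRecord | str) -> list[MotifHit]:
    """All matches of the loose classical monopartite NLS K-[KR]-x-[KR].

    Overlapping hits are all reported, in ascending start order.  This is the
    consensus recognized by the importin-alpha major binding site (e.g. the
    C-terminal KRRK of Acl1).
    """
    residues = _protein_residues(seq)
    hits = []
    for i in range(len(residues) - 3):
        w = residues[i : i + 4]
        if w[0] == "K" and w[1] in "KR" and w[3] in "KR":
            hits.append(MotifHit(kind="cNLS", start=i + 1, end=i + 4, match=w))
    return hits


def scan_bpy_nls(
    seq: SequenceRecord | str,
    window: int = 20,
    min_basic: int = 4,
    hydrophobic: set[str] = HYDROPHOBIC,
) -> list[MotifHit]:
    """All basic-PY NLS matches: basic stretch + R/K/H-x(2-5)-P-[Y/phi].

    A hit requires an anchor residue in {R, K, H}, a gap of 2-5 arbitrary
    residues, then P immediately followed by Y or a hydrophobic residue, and
    at least ``min_basic`` residues from {K, R, H} among the up-to-``window``
    residues immediately preceding the anchor.  The hit spans from the start
    of that upstream window through the Y/phi position.  Hits are reported in
    ascending (start, end) order; overlaps are all kept.
    """
    if window < 1 or min_basic < 0:
        raise ValueError("window must be >=1 and min_basic >=0")
    residues = _protein_residues(seq)
    n = len(residues)
    phi = set(hydrophobic) | {"Y"}
    hits = []
    for a in range(n):  # 0-based anchor index
        if residues[a] not in BASIC:
            continue
        for gap in range(2, 6):
            p = a + gap + 1
            y = p + 1
            if y >= n:
                break
            if residues[p] != "P" or residues[y] not in phi:
                continue
            w_start = max(0, a - window)
            upstream = residues[w_start:a]
            n_basic = sum(1 for r in upstream if r in BASIC)
            if n_basic < min_basic:
                continue
            start = w_start + 1 if upstream else a + 1
            hits.append(
                MotifHit(
                    kind="bPY",
                    start=start,
                    end=y + 1,
                    match=residues[start - 1 : y + 1],
                    anchor_pos=a + 1,
                    py_pos=(p + 1, y + 1),
                    n_basic=n_basic,
                    c_term_distance=n - (y + 1),
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.anchor_pos or 0))
    return hits


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3' (ACGT only)."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name in ("forward", "reverse"):
            s = getattr(self, name).upper()
            if not s or set(s) - DNA_ALPHABET:
                raise ValueError(f"{name} primer must be non-empty ACGT")
            object.__setattr__(self, name, s)


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on the plus strand, primers included."""

    start: int  # 1-based position of the forward primer's 5' end
    end: int  # 1-based position of the reverse primer's 5' end on the template
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.length != self.end - self.start + 1:
            raise ValueError("inconsistent amplicon coordinates")


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    """Overlapping 0-based occurrences of needle in haystack."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def predict_amplicon(
    template: SequenceRecord | str, primers: PrimerPair
) -> list[Amplicon]:
    """Exact-match amplicons of a primer pair on a linear plus-strand template.

    For every plus-strand occurrence of the forward primer and every
    occurrence of the reverse complement of the reverse primer starting at or
    after the forward primer's 3' end + 1, an amplicon spanning the forward
    5' end through the reverse-complement 3' end (inclusive) is emitted,
    sorted by length.  Matching is case-insensitive with no mismatches or
    degenerate bases.  An absent primer yields an empty list.
    """
    if isinstance(template, SequenceRecord):
        if template.kind != "nucleotide":
            raise ValueError(f"{template.id!r}: nucleotide template required")
        tpl = template.residues
    else:
        tpl = SequenceRecord("template", str(template), "nucleotide").residues
    fwd = primers.forward
    rev_site = str(Seq(primers.reverse).reverse_complement())
    fwd_hits = list(_find_all(tpl, fwd))
    rev_hits = list(_find_all(tpl, rev_site))
    products = []
    for f in fwd_hits:
        f_end = f + len(fwd)  # 0-based index just past the forward 3' end
        for r in rev_hits:
            if r < f_end:
                continue
            end0 = r + len(rev_site) - 1
            products.append(
                Amplicon(
                    start=f + 1,
                    end=end0 + 1,
                    length=end0 - f + 1,
                    sequence=tpl[f : end0 + 1],
                )
            )
    products.sort(key=lambda a: (a.length, a.start))
    return products


# ---------------------------------------------------------------------------
# FASTA I/O and retrieval
# ---------------------------------------------------------------------------

def read_fasta(path, kind: str = "protein") -> list[SequenceRecord]:
    from Bio import SeqIO

    return [
        SequenceRecord(rec.id, str(rec.seq), kind)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def fetch_uniprot_fasta(accession: str, timeout: float = 30.0) -> SequenceRecord:
    """Download one protein sequence from UniProtKB (requires network)."""
    import io
    import urllib.request

    from Bio import SeqIO

    url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode("utf-8")
    rec = next(SeqIO.parse(io.StringIO(text), "fasta"))
    return SequenceRecord(accession, str(rec.seq), "protein")
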