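import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proxiome.seqfeatures import (
    BJELLQVIST,
    HYDROPHOBIC,
    PrimerPair,
    SequenceRecord,
    isoelectric_point,
    molecular_weight,
    net_charge,
    predict_amplicon,
    scan_bpy_nls,
    scan_cnls,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng, min_len=5, max_len=40):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AA), size=n))


# ---------------------------------------------------------------------------
# charge / pI / mass
# ---------------------------------------------------------------------------

def charge_grid_oracle(seq: str, pka=BJELLQVIST, step=1e-4):
    """Independent pI oracle: zero crossing of the charge on a fine pH grid."""
    grid = np.arange(0.0, 14.0 + step, step)
    pos = [pka.n_terminus] + [
        {"K": pka.K, "R": pka.R, "H": pka.H}[a] for a in seq if a in "KRH"
    ]
    neg = [pka.c_terminus] + [
        {"D": pka.D, "E": pka.E, "C": pka.C, "Y": pka.Y}[a] for a in seq if a in "DECY"
    ]
    charge = np.zeros_like(grid)
    for pk in pos:
        charge += 1.0 / (1.0 + 10.0 ** (grid - pk))
    for pk in neg:
        charge -= 1.0 / (1.0 + 10.0 ** (pk - grid))
    i = int(np.argmax(charge < 0))  # first pH with negative charge
    return 0.5 * (grid[i - 1] + grid[i])


class TestNetCharge:
    def test_c_terminus_half_protonated_at_its_pka(self):
        # at pH = pKa(C-term), the carboxyl group contributes exactly -0.5
        for aa in "AGLS":
            expected_nterm = 1.0 / (1.0 + 10.0 ** (BJELLQVIST.c_terminus - BJELLQVIST.n_terminus))
            assert net_charge(aa, BJELLQVIST.c_terminus) == pytest.approx(
                expected_nterm - 0.5, abs=1e-12
            )

    def test_polyalanine_matches_termini_only_closed_form(self):
        # poly-A has no ionizable side chains; hand-evaluated two-term formula
        expected = 1.0 / (1.0 + 10.0 ** (7.0 - BJELLQVIST.n_terminus)) - 1.0 / (
            1.0 + 10.0 ** (BJELLQVIST.c_terminus - 7.0)
        )
        assert net_charge("A" * 10, 7.0) == pytest.approx(expected, abs=1e-12)

    def test_charge_strictly_decreasing_in_ph(self, rng):
        for _ in range(100):
            seq = random_peptide(rng)
            charges = [net_charge(seq, ph) for ph in np.arange(0.0, 14.01, 0.5)]
            assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_nucleotide_input_rejected(self):
        rec = SequenceRecord("t", "ACGT", "nucleotide")
        with pytest.raises(ValueError):
            net_charge(rec, 7.0)


class TestIsoelectricPoint:
    def test_glycylglycine_pi_is_midpoint_of_termini(self):
        # only the two termini ionize: charge is antisymmetric about the
        # midpoint of their pKa values
        assert isoelectric_point("GG") == pytest.approx(
            (BJELLQVIST.n_terminus + BJELLQVIST.c_terminus) / 2, abs=1e-4
        )

    def test_bisection_agrees_with_grid_scan(self, rng):
        for _ in range(100):
            seq = random_peptide(rng)
            assert isoelectric_point(seq) == pytest.approx(
                charge_grid_oracle(seq), abs=2e-4
            )

    def test_monotone_under_basic_and_acidic_appends(self, rng):
        for _ in range(30):
            seq = random_peptide(rng, 5, 20)
            pi = isoelectric_point(seq)
            assert isoelectric_point(seq + "K") >= pi - 1e-4
            assert isoelectric_point(seq + "D") <= pi + 1e-4

    def test_agrees_with_biopython_reference(self, rng):
        # Biopython's IsoelectricPoint uses the same pKa family; anchor the
        # termini at G to avoid its residue-specific terminal pKa values
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        for _ in range(25):
            seq = "G" + random_peptide(rng, 5, 30) + "G"
            # widen Biopython's default search bracket so acidic/basic
            # peptides are not clamped at its [4.05, 12] limits
            assert isoelectric_point(seq) == pytest.approx(
                IsoelectricPoint(seq).pi(min_=0.0, max_=14.0), abs=0.01
            )


class TestMolecularWeight:
    def test_glycine_mass(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.text(alphabet=AA, min_size=1, max_size=30),
        b=st.text(alphabet=AA, min_size=1, max_size=30),
    )
    def test_condensation_identity(self, a, b):
        # peptide-bond formation releases one water
        assert molecular_weight(a + b) == pytest.approx(
            molecular_weight(a) + molecular_weight(b) - 18.0153, abs=1e-6
        )

    def test_permutation_invariance_and_positivity(self, rng):
        seq = random_peptide(rng, 10, 30)
        shuffled = "".join(rng.permutation(list(seq)))
        assert molecular_weight(seq) == pytest.approx(molecular_weight(shuffled))
        assert molecular_weight(seq) > 0


# ---------------------------------------------------------------------------
# NLS scanners
# ---------------------------------------------------------------------------

def cnls_enumeration(seq: str):
    """Exhaustive window enumeration: K-[KR]-x-[KR] at every position."""
    return [
        (i + 1, i + 4)
        for i in range(len(seq) - 3)
        if re.fullmatch("K[KR].[KR]", seq[i : i + 4])
    ]


def bpy_enumeration(seq: str, window: int, min_basic: int):
    """Exhaustive enumeration of the basic-PY signature."""
    phi = HYDROPHOBIC | {"Y"}
    out = []
    for a in range(len(seq)):
        if seq[a] not in "KRH":
            continue
        for gap in (2, 3, 4, 5):
            p, y = a + gap + 1, a + gap + 2
            if y >= len(seq):
                continue
            if seq[p] == "P" and seq[y] in phi:
                w = seq[max(0, a - window) : a]
                if sum(c in "KRH" for c in w) >= min_basic:
                    out.append((max(0, a - window) + 1, y + 1, a + 1))
    return sorted(out)


class TestScanCnls:
    def test_c_terminal_krrk(self):
        seq = "MSTAQE" + "KRRK"
        hits = scan_cnls(seq)
        assert [(h.start, h.end) for h in hits] == [(7, 10)]
        assert hits[0].match == "KRRK"

    def test_polyalanine_has_no_hits(self):
        assert scan_cnls("AAAA" * 5) == []

    def test_overlapping_hits_all_reported(self):
        hits = scan_cnls("KKKKK")  # windows 1-4 and 2-5 both match
        assert [(h.start, h.end) for h in hits] == [(1, 4), (2, 5)]

    def test_matches_exhaustive_enumeration(self, rng):
        basic_rich = list("KRAGSTNQ")
        for _ in range(200):
            n = int(rng.integers(4, 60))
            seq = "".join(rng.choice(basic_rich, size=n))
            assert [(h.start, h.end) for h in scan_cnls(seq)] == cnls_enumeration(seq)
            for h in scan_cnls(seq):
                assert h.match == seq[h.start - 1 : h.end]


# Synthetic stand-in for the C-terminal bPY-NLS segment of Bcl1 (residues
# 364-389): 26 residues with eight lysines and three arginines, the anchor
# arginine at 385, proline at 388 and tyrosine at 389 (positions here given
# in full-length coordinates; the real segment sequence is not reproduced).
SYNTHETIC_BCL1_364C = "NKKTKRSKKGKSKNKGRASGSRNSPY"
assert len(SYNTHETIC_BCL1_364C) == 26
assert SYNTHETIC_BCL1_364C.count("K") == 8 and SYNTHETIC_BCL1_364C.count("R") == 3


class TestScanBpyNls:
    def test_synthetic_bcl1_segment_has_exactly_one_c_terminal_hit(self):
        # pad to full length so coordinates match the 389-residue protein
        seq = "AGSTN" * 72 + "AGS" + SYNTHETIC_BCL1_364C
        assert len(seq) == 389
        hits = scan_bpy_nls(seq, window=20, min_basic=4)
        assert len(hits) == 1
        h = hits[0]
        assert h.anchor_pos == 385
        assert h.py_pos == (388, 389)
        assert h.end == 389 and h.near_c_terminus
        assert h.n_basic >= 4

    def test_signature_without_basic_stretch_is_rejected(self):
        # R-x2-P-Y embedded in poly-alanine: no basic-enriched context
        seq = "A" * 30 + "RAAPY" + "A" * 5
        assert scan_bpy_nls(seq, window=20, min_basic=4) == []

    def test_terminal_pa_is_not_a_signature(self):
        # models the Y->A exchange that abolishes importin binding
        seq = "KKKRKKRKKK" + "RAAPA"
        assert scan_bpy_nls(seq, window=20, min_basic=4) == []
        # the unmutated counterpart is accepted
        assert scan_bpy_nls("KKKRKKRKKK" + "RAAPY", window=20, min_basic=4)

    @pytest.mark.parametrize("window,min_basic", [(5, 1), (10, 2), (20, 4)])
    def test_matches_exhaustive_enumeration(self, rng, window, min_basic):
        alphabet = list("KRHAPYLGSTN")
        for _ in range(150):
            n = int(rng.integers(8, 70))
            seq = "".join(rng.choice(alphabet, size=n))
            got = sorted((h.start, h.end, h.anchor_pos) for h in scan_bpy_nls(seq, window, min_basic))
            assert got == bpy_enumeration(seq, window, min_basic)


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def revcomp(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


class TestPredictAmplicon:
    F20 = "ACCCCAGTTTCTCACAACGA"
    R19 = "GCAACAGCCAAACACAAGA"

    def test_constructed_template_yields_known_length(self, rng):
        spacer = "".join(rng.choice(list("ACGT"), size=20))
        template = self.F20 + spacer + revcomp(self.R19)
        products = predict_amplicon(template, PrimerPair(self.F20, self.R19))
        assert len(products) == 1
        a = products[0]
        assert (a.start, a.end, a.length) == (1, 59, 59)
        assert a.sequence == template

    def test_absent_forward_primer_gives_empty_list(self):
        template = "A" * 30 + revcomp(self.R19)
        assert predict_amplicon(template, PrimerPair(self.F20, self.R19)) == []

    def test_lengths_invariant_to_downstream_extension(self, rng):
        spacer = "".join(rng.choice(list("ACGT"), size=33))
        core = self.F20 + spacer + revcomp(self.R19)
        tail = "".join(rng.choice(list("ACGT"), size=50))
        lengths = lambda t: [a.length for a in predict_amplicon(t, PrimerPair(self.F20, self.R19))]
        assert lengths("TT" + core + tail) == lengths(core)

    def test_multiple_products_reported_sorted_by_length(self):
        f, r = "ACGTACGTAC", "TTTTGGGGCC"
        template = f + "AA" + revcomp(r) + "CC" + revcomp(r)
        products = predict_amplicon(template, PrimerPair(f, r))
        assert [a.length for a in products] == sorted(a.length for a in products)
        assert len(products) == 2

    def test_reverse_site_before_forward_not_amplified(self):
        f, r = "ACGTACGTAC", "TTTTGGGGCC"
        template = revcomp(r) + "AAAA" + f
        assert predict_amplicon(template, PrimerPair(f, r)) == []

    def test_case_insensitive_matching(self):
        f, r = "ACGTACGTAC", "TTTTGGGGCC"
        template = (f + "AA" + revcomp(r)).lower()
        assert len(predict_amplicon(template, PrimerPair(f.lower(), r))) == 1
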