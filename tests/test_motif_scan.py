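"""Motif scanning, IQ67 assembly and family classification."""

import itertools
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iq67kit import motif_scan as ms
from iq67kit.records import ProteinRecord, SequenceError

# Independent regex oracle for the consensus patterns. The scanner itself
# uses per-position set membership, so agreement is a genuine cross-check.
ORACLE_RE = {
    ms.MotifClass.IQ_STRICT: re.compile(r"(?=IQ.{3}RG.{3}R)"),
    ms.MotifClass.IQ_RELAXED: re.compile(r"(?=[ILV]Q.{3}R.{3}R[RK])"),
    ms.MotifClass.M_1_8_14: re.compile(r"(?=[FILVW].{6}[FAILVW].{5}[FILVW])"),
    ms.MotifClass.M_1_5_10: re.compile(r"(?=[FILVW].{3}[FILV].{4}[FILVW])"),
}


def oracle_starts(seq: str, cls: ms.MotifClass) -> list[int]:
    return [m.start() for m in ORACLE_RE[cls].finditer(seq)]


IQ67_BLOCK = "IQAAARGAAAR" + "A" * 11 + "IQAAARGAAAR" + "A" * 15 + "IQAAARGAAAR"


@pytest.mark.parametrize(
    "seq,allow_relaxed,expected",
    [
        ("IQAAARGAAAR", False, [(ms.MotifClass.IQ_STRICT, 0, 11)]),
        ("IQAAARAAARR", True, [(ms.MotifClass.IQ_RELAXED, 0, 11)]),
        ("IQAAARAAARR", False, []),
        ("AAAAAAAAAAA", True, []),
        # strict-over-relaxed precedence: a window matching both is strict only
        ("IQAAARGAARR", True, [(ms.MotifClass.IQ_STRICT, 0, 11)]),
    ],
)
def test_scan_iq_examples(seq, allow_relaxed, expected):
    hits = ms.scan_iq(seq, allow_relaxed=allow_relaxed)
    assert [(h.motif_class, h.start, h.end) for h in hits] == expected
    for h in hits:
        assert h.match == seq[h.start:h.end]


@pytest.mark.parametrize(
    "seq,cls,n",
    [
        ("FAAAAAAFAAAAAF", ms.MotifClass.M_1_8_14, 1),
        ("FAAAAAAFAAAAAF", ms.MotifClass.M_1_5_10, 0),
        ("FAAAFAAAAF", ms.MotifClass.M_1_5_10, 1),
        ("FAAAFAAAAF", ms.MotifClass.M_1_8_14, 0),
    ],
)
def test_scan_accessory_examples(seq, cls, n):
    hits = [h for h in ms.scan_accessory(seq) if h.motif_class is cls]
    assert len(hits) == n


def test_invalid_residue_names_position():
    with pytest.raises(SequenceError, match="position 3"):
        ms.scan_iq("AA*AA")


def test_x_matches_wildcard_but_never_constrained_positions():
    assert len(ms.scan_iq("IQXXXRGXXXR")) == 1       # X at wildcard slots
    assert ms.scan_iq("XQAAARGAAAR") == []            # X at the I anchor
    assert ms.scan_iq("IQAAAXGAAAR") == []            # X at the R slot


class TestAssemble:
    def _hits(self, coords):
        return [ms.MotifHit(ms.MotifClass.IQ_STRICT, s, e, "IQAAARGAAAR")
                for s, e in coords]

    def test_exact_spacing_yields_domain(self):
        doms = ms.assemble_iq67(self._hits([(0, 11), (22, 33), (48, 59)]))
        assert len(doms) == 1
        d = doms[0]
        assert (d.domain_start, d.domain_end, d.gap1, d.gap2) == (0, 59, 11, 15)
        assert d.span == 11 + 11 + 11 + 15 + 11

    def test_off_by_one_spacing_rejected(self):
        assert ms.assemble_iq67(self._hits([(0, 11), (21, 32), (47, 58)])) == []

    def test_four_hits_brute_force(self):
        """Exactly the triples valid under brute force over C(4,3) are reported."""
        coords = [(0, 11), (22, 33), (48, 59), (85, 96)]
        hits = self._hits(coords)
        expected = sum(
            1 for trip in itertools.combinations(hits, 3)
            if trip[1].start - trip[0].end == 11 and trip[2].start - trip[1].end == 15
        )
        assert expected == 1
        assert len(ms.assemble_iq67(hits)) == expected

    def test_accessory_counts_overlap_span(self):
        hits = self._hits([(0, 11), (22, 33), (48, 59)])
        hits.append(ms.MotifHit(ms.MotifClass.M_1_8_14, 12, 26, "F" * 14))
        hits.append(ms.MotifHit(ms.MotifClass.M_1_5_10, 70, 80, "F" * 10))  # outside
        d = ms.assemble_iq67(hits)[0]
        assert (d.n_1_8_14, d.n_1_5_10) == (1, 0)

    def test_negative_spacing_rejected(self):
        with pytest.raises(ValueError):
            ms.assemble_iq67([], spacings=(-1, 15))


class TestClassify:
    def test_planted_domain_is_sun(self):
        rec = ProteinRecord.from_raw("p1", "M" + IQ67_BLOCK + "M" * 20)
        call = ms.classify_protein(rec)
        assert call.family is ms.Family.SUN
        assert len(call.domains) == 1
        assert call.domains[0].domain_start == 1

    def test_wrong_middle_spacer_is_other_iq(self):
        block = "IQAAARGAAAR" + "A" * 12 + "IQAAARGAAAR" + "A" * 15 + "IQAAARGAAAR"
        call = ms.classify_protein(ProteinRecord.from_raw("p2", "M" + block))
        assert call.family is ms.Family.OTHER_IQ
        assert "spacing mismatch" in call.notes

    def test_poly_alanine_is_none(self):
        call = ms.classify_protein(ProteinRecord.from_raw("p3", "A" * 300))
        assert call.family is ms.Family.NONE
        assert call.n_iq == 0

    def test_family_invariants(self, small_proteome):
        records, _ = small_proteome
        for rec in records:
            call = ms.classify_protein(rec)
            assert (call.family is ms.Family.SUN) == call.has_iq67
            if call.family is ms.Family.OTHER_IQ:
                assert call.n_iq >= 1 and not call.has_iq67
            if call.family is ms.Family.NONE:
                assert call.n_iq == 0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=0, max_size=60))
def test_scanner_equals_brute_force_on_short_sequences(seq):
    """On sequences <= 60 aa, hits match an independent regex enumeration."""
    strict = oracle_starts(seq, ms.MotifClass.IQ_STRICT)
    relaxed = [s for s in oracle_starts(seq, ms.MotifClass.IQ_RELAXED)
               if s not in strict]
    got = ms.scan_iq(seq, allow_relaxed=True)
    assert [h.start for h in got if h.motif_class is ms.MotifClass.IQ_STRICT] == strict
    assert [h.start for h in got if h.motif_class is ms.MotifClass.IQ_RELAXED] == relaxed
    acc = ms.scan_accessory(seq)
    for cls in (ms.MotifClass.M_1_8_14, ms.MotifClass.M_1_5_10):
        assert [h.start for h in acc if h.motif_class is cls] == oracle_starts(seq, cls)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=11, max_size=120))
def test_pattern_soundness(seq):
    """Every reported hit substring re-satisfies its consensus (regex oracle)."""
    for h in ms.scan_iq(seq) + ms.scan_accessory(seq):
        assert ORACLE_RE[h.motif_class].match(seq[h.start:]), h


class TestScanProteome:
    def test_planted_recovery_and_tables(self, small_cfg, small_proteome, tmp_path):
        from iq67kit.records import write_fasta
        records, truth = small_proteome
        fasta = tmp_path / "prot.fasta"
        write_fasta(records, fasta)
        calls, hits = ms.scan_proteome(fasta)
        assert len(calls) == len(records)
        assert list(calls["protein_id"]) == [r.id for r in records]
        merged = calls.merge(truth, on="protein_id")
        assert (merged["family"] == merged["class"]).all()
        # every SUN call carries a 1-based domain coordinate string
        sun = calls[calls["family"] == "SUN"]
        assert (sun["domain_coords"] != "").all()

    def test_empty_fasta(self, tmp_path):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        calls, hits = ms.scan_proteome(fasta)
        assert calls.empty and hits.empty

    def test_deterministic_tsv_bytes(self, small_proteome, tmp_path):
        from iq67kit.records import write_fasta
        records, _ = small_proteome
        fasta = tmp_path / "prot.fasta"
        write_fasta(records, fasta)
        outs = []
        for k in range(2):
            calls, hits = ms.scan_proteome(fasta)
            p = tmp_path / f"calls{k}.tsv"
            calls.to_csv(p, sep="\t", index=False)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]


def test_sun_call_contains_exactly_spaced_domain(small_proteome):
    """Spacing exactness: every SUN call has a domain with the configured gaps."""
    records, _ = small_proteome
    for rec in records:
        call = ms.classify_protein(rec, spacings=(11, 15))
        if call.family is ms.Family.SUN:
            assert any(d.gap1 == 11 and d.gap2 == 15 for d in call.domains)
            for d in call.domains:
                h1, h2, h3 = d.iq_hits
                assert h2.start - h1.end == 11 and h3.start - h2.end == 15
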