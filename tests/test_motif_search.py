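import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mipscreen.core_io import ProteinEntry
from mipscreen.motif_search import (
    MotifQuery,
    compile_signature,
    parse_signature,
    reverse_tokens,
    search_proteome,
    search_sequence,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_positions(seq, tokens):
    """Naive position-by-position matcher, independent of the regex path."""
    k = len(tokens)
    out = []
    for s in range(len(seq) - k + 1):
        ok = True
        for t, aa in zip(tokens, seq[s : s + k]):
            if t == "x":
                continue
            if t.startswith("["):
                if aa not in t[1:-1]:
                    ok = False
                    break
            elif aa != t:
                ok = False
                break
        if ok:
            out.append(s)
    return out


class TestParseSignature:
    def test_tokens(self):
        assert parse_signature("[FHY]xWxxKxx[FHY]") == [
            "[FHY]", "x", "W", "x", "x", "K", "x", "x", "[FHY]",
        ]

    def test_reverse_is_token_reversal(self):
        assert "".join(reverse_tokens(parse_signature("WPxxxxxW"))) == "WxxxxxPW"

    @pytest.mark.parametrize(
        "bad, msg",
        [
            ("[FH", "unbalanced"),
            ("A[]B", "empty"),
            ("A*B", "illegal"),
            ("", "empty"),
            ("[Fz]", "illegal"),
        ],
    )
    def test_parse_errors(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            parse_signature(bad)

    def test_uppercase_X_is_literal(self):
        # 'x' is the wildcard; 'X' matches only the unknown-residue letter
        m = compile_signature("AXA", "forward")["forward"]
        assert m.search("AXA")
        assert not m.search("AGA")


class TestCompile:
    def test_density_signature_matches_constructed_example(self):
        m = compile_signature("[FHY]xWxxKxx[FHY]", "forward")["forward"]
        assert m.search("FAWGGKCCY")

    def test_token_count_is_strict(self):
        m = compile_signature("WPxxxxxW", "forward")["forward"]
        assert m.search("WPABCDEW".replace("B", "C"))  # 5 wildcards
        assert not m.search("WPACDW")  # only 4 residues between anchors

    def test_case_insensitive_over_sequences(self):
        matchers = compile_signature("WxK", "forward")
        hits = search_sequence("p", "awgk", matchers)
        assert [(h.start, h.end) for h in hits] == [(1, 4)]

    def test_unknown_direction(self):
        with pytest.raises(ValueError, match="direction"):
            compile_signature("WxK", "sideways")


class TestSearchProteome:
    def _proteome(self, seqs):
        return [ProteinEntry(id=f"p{i}", sequence=s) for i, s in enumerate(seqs)]

    def test_length_window_filters_scan(self):
        motif = "FAWGGKCCY"  # instance of [FHY]xWxxKxx[FHY]
        seqs = [
            ("A" * 50 + motif + "A" * 41),      # length 100: outside window
            ("A" * 120 + motif + "A" * 101),    # length 230: inside
            ("A" * 150 + motif + "A" * 101),    # length 260: inside
        ]
        query = MotifQuery("[FHY]xWxxKxx[FHY]", (220, 280), "forward")
        hits, matched = search_proteome(self._proteome(seqs), query)
        assert matched == ["p1", "p2"]
        assert all(h.matched_seq == motif for h in hits)
        # window is inclusive on both bounds
        edge = self._proteome([("A" * 211 + motif), (motif + "A" * 271)])
        hits, matched = search_proteome(edge, query)
        assert matched == ["p0", "p1"]

    def test_perfect_match_outside_window_is_dropped(self):
        seq = "A" * 40 + "WPCCCCCW" + "A" * 52  # length 100
        query = MotifQuery("WPxxxxxW", (128, 147), "forward")
        hits, _ = search_proteome(self._proteome([seq]), query)
        assert hits == []

    def test_window_disable_flag(self):
        seq = "A" * 40 + "WPCCCCCW" + "A" * 52
        query = MotifQuery("WPxxxxxW", (128, 147), "forward")
        hits, _ = search_proteome(
            self._proteome([seq]), query, apply_length_filter=False
        )
        assert len(hits) == 1

    def test_reverse_only_instance_found_in_both_mode(self):
        # plant the token-reversed pattern WxxxxxPW only
        seq = "A" * 30 + "WCCCCCPW" + "A" * 100
        query = MotifQuery("WPxxxxxW", (100, 200), "both")
        hits, _ = search_proteome(self._proteome([seq]), query)
        assert len(hits) == 1 and hits[0].direction == "reverse"
        # oracle agreement on the reversed token list
        assert oracle_positions(seq, reverse_tokens(parse_signature("WPxxxxxW"))) == [
            hits[0].start
        ]

    def test_overlapping_matches_all_reported(self):
        matchers = compile_signature("AxA", "forward")
        hits = search_sequence("p", "AAAAA", matchers)
        assert [h.start for h in hits] == [0, 1, 2]

    def test_no_wildcards_reduces_to_substring_search(self):
        seq = "MKWLEMKWLE"
        matchers = compile_signature("MKWLE", "forward")
        hits = search_sequence("p", seq, matchers)
        starts = [i for i in range(len(seq)) if seq.startswith("MKWLE", i)]
        assert [h.start for h in hits] == starts

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_equivalence_with_oracle_on_random_proteomes(self, seed):
        rng = np.random.default_rng(seed)
        sigs = ["[FHY]xWxxKxx[FHY]", "WPxxxxxW", "KxK", "[AC]x[DE]", "MKW"]
        sig = sigs[int(rng.integers(len(sigs)))]
        direction = ["forward", "reverse", "both"][int(rng.integers(3))]
        proteome = [
            ProteinEntry(
                id=f"p{i}",
                sequence="".join(
                    rng.choice(list(AA), size=int(rng.integers(10, 400)))
                ),
            )
            for i in range(int(rng.integers(1, 8)))
        ]
        query = MotifQuery(sig, None, direction)
        hits, _ = search_proteome(proteome, query)
        got = {(h.protein_id, h.start, h.direction) for h in hits}
        tokens = parse_signature(sig)
        want = set()
        for e in proteome:
            if direction in ("forward", "both"):
                want |= {(e.id, s, "forward") for s in oracle_positions(e.sequence, tokens)}
            if direction in ("reverse", "both"):
                want |= {
                    (e.id, s, "reverse")
                    for s in oracle_positions(e.sequence, reverse_tokens(tokens))
                }
        assert got == want

    def test_window_widening_never_removes_hits(self, rng):
        proteome = [
            ProteinEntry(
                id=f"p{i}",
                sequence="".join(rng.choice(list(AA), size=int(rng.integers(50, 300)))),
            )
            for i in range(20)
        ]
        narrow = MotifQuery("KxK", (100, 200), "forward")
        wide = MotifQuery("KxK", (50, 300), "forward")
        h_narrow, _ = search_proteome(proteome, narrow)
        h_wide, _ = search_proteome(proteome, wide)
        assert set(h_narrow) <= set(h_wide)

    def test_hit_invariants(self, rng):
        proteome = [
            ProteinEntry(
                id=f"p{i}",
                sequence="".join(rng.choice(list(AA), size=120)),
            )
            for i in range(10)
        ]
        query = MotifQuery("[FHY]xWxxKxx[FHY]", None, "both")
        hits, _ = search_proteome(proteome, query)
        k = query.n_tokens
        seqs = {e.id: e.sequence for e in proteome}
        for h in hits:
            assert h.end - h.start == k
            assert seqs[h.protein_id][h.start : h.end] == h.matched_seq
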