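import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trackprov import ChainIndex, generate_chain, lift_interval, read_chain
from trackprov.errors import ChainIntegrityError, ChainParseError, ConfigurationError
from trackprov.tracks import GenomicInterval

from .oracles import brute_force_lift, per_base_map


def _iv(chrom, start, end):
    return GenomicInterval(chrom=chrom, start=start, end=end)


def _write_chain(tmp_path, text, name="test.chain"):
    path = tmp_path / name
    path.write_text(text)
    return path


IDENTITY = "chain 100 tA 1000 + 0 1000 qA 1000 + 0 1000 1\n1000\n"
GAPPED = "chain 90 tA 1000 + 0 1000 qA 1010 + 0 1010 2\n50 0 10\n950\n"


class TestReadChain:
    def test_single_full_block_identity(self, tmp_path):
        (chain,) = read_chain(_write_chain(tmp_path, IDENTITY))
        assert chain.blocks == ((1000, 0, 0),)
        assert (chain.t_name, chain.q_name) == ("tA", "qA")
        assert per_base_map(chain) == {i: ("qA", i) for i in range(1000)}

    def test_gap_arithmetic(self, tmp_path):
        (chain,) = read_chain(_write_chain(tmp_path, GAPPED))
        assert chain.blocks == ((50, 0, 10), (950, 0, 0))
        mapping = per_base_map(chain)
        assert mapping[49] == ("qA", 49)
        assert mapping[50] == ("qA", 60)  # +10 query insertion after 50 bases

    def test_block_sum_inconsistency_rejected(self, tmp_path):
        bad = "chain 10 tA 1000 + 0 1000 qA 1000 + 0 1000 7\n999\n"
        with pytest.raises(ChainIntegrityError) as err:
            read_chain(_write_chain(tmp_path, bad))
        assert err.value.chain_id == 7

    def test_truncated_file_is_a_parse_error(self, tmp_path):
        truncated = "chain 10 tA 1000 + 0 1000 qA 1000 + 0 1000 1\n50 0 10\n"
        with pytest.raises(ChainParseError):
            read_chain(_write_chain(tmp_path, truncated))

    def test_short_header_names_line(self, tmp_path):
        with pytest.raises(ChainParseError) as err:
            read_chain(_write_chain(tmp_path, "chain 10 tA 1000 +\n"))
        assert err.value.line_no == 1

    def test_multiple_chains(self, tmp_path):
        chains = read_chain(_write_chain(tmp_path, IDENTITY + GAPPED))
        assert [c.chain_id for c in chains] == [1, 2]


class TestLiftInterval:
    def test_identity_lift(self, tmp_path):
        index = ChainIndex.from_file(_write_chain(tmp_path, IDENTITY))
        result = lift_interval(_iv("tA", 10, 20), index)
        assert result.status == "mapped"
        assert (result.mapped_interval.start, result.mapped_interval.end) == (10, 20)
        assert result.matched_fraction == 1.0

    def test_offset_after_query_gap(self, tmp_path):
        index = ChainIndex.from_file(_write_chain(tmp_path, GAPPED))
        result = lift_interval(_iv("tA", 60, 70), index)
        assert result.status == "mapped"
        assert (result.mapped_interval.start, result.mapped_interval.end) == (70, 80)

    def test_interval_straddling_query_gap_splits(self, tmp_path):
        index = ChainIndex.from_file(_write_chain(tmp_path, GAPPED))
        result = lift_interval(_iv("tA", 40, 60), index)
        assert result.status == "split"
        assert result.matched_fraction == 1.0  # all bases map, discontiguously

    def test_partial_vs_mapped_depends_on_min_match(self, tmp_path):
        # 1000-base interval straddles a 100-base target gap: 900 bases align
        # onto one contiguous query run (dq = 0), fraction 0.90
        text = "chain 80 tA 2000 + 0 2000 qA 1900 + 0 1900 3\n500 100 0\n1400\n"
        index = ChainIndex.from_file(_write_chain(tmp_path, text))
        iv = _iv("tA", 0, 1000)
        strict = lift_interval(iv, index, min_match=0.95)
        assert strict.status == "partial_below_threshold"
        assert strict.matched_fraction == pytest.approx(0.90)
        loose = lift_interval(iv, index, min_match=0.85)
        assert loose.status == "mapped"
        assert (loose.mapped_interval.start, loose.mapped_interval.end) == (0, 900)

    def test_unmapped_without_overlapping_chain(self, tmp_path):
        index = ChainIndex.from_file(_write_chain(tmp_path, IDENTITY))
        assert lift_interval(_iv("tB", 0, 10), index).status == "unmapped"

    def test_interval_inside_target_gap_is_unmapped(self, tmp_path):
        text = "chain 80 tA 2000 + 0 2000 qA 1900 + 0 1900 3\n500 100 0\n1400\n"
        index = ChainIndex.from_file(_write_chain(tmp_path, text))
        assert lift_interval(_iv("tA", 520, 580), index).status == "unmapped"

    def test_negative_strand_reflected_to_plus(self, tmp_path):
        # query strand '-': coordinates are on the reversed sequence
        text = "chain 50 tA 100 + 0 100 qA 100 - 0 100 4\n100\n"
        index = ChainIndex.from_file(_write_chain(tmp_path, text))
        result = lift_interval(_iv("tA", 10, 20), index)
        assert result.status == "mapped"
        assert (result.mapped_interval.start, result.mapped_interval.end) == (80, 90)
        (chain,) = index.chains
        assert brute_force_lift(_iv("tA", 10, 20), [chain])[1] == ("qA", 80, 90)

    def test_best_chain_by_score_then_overlap_then_id(self, tmp_path):
        # two chains over the same span: the higher-scoring one wins
        low = "chain 10 tA 1000 + 0 1000 qA 1000 + 0 1000 1\n1000\n"
        high = "chain 99 tA 1000 + 0 1000 qB 2000 + 500 1500 2\n1000\n"
        index = ChainIndex.from_file(_write_chain(tmp_path, low + high))
        result = lift_interval(_iv("tA", 0, 10), index)
        assert result.chain_id == 2
        assert result.mapped_interval.chrom == "qB"
        assert result.mapped_interval.start == 500

    def test_min_match_validation(self, tmp_path):
        index = ChainIndex.from_file(_write_chain(tmp_path, IDENTITY))
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ConfigurationError):
                lift_interval(_iv("tA", 0, 10), index, min_match=bad)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 990), st.integers(1, 100))
    def test_identity_chain_is_identity_on_subintervals(
        self, tmp_path_factory, start, length
    ):
        tmp = tmp_path_factory.mktemp("idc")
        index = ChainIndex.from_file(_write_chain(tmp, IDENTITY))
        end = min(start + length, 1000)
        result = lift_interval(_iv("tA", start, end), index)
        assert result.status == "mapped"
        assert (result.mapped_interval.start, result.mapped_interval.end) == (start, end)

    def test_matched_fraction_length_weighted_conservation(self, tmp_path):
        text = "chain 80 tA 2000 + 0 2000 qA 1900 + 0 1900 3\n500 100 0\n1400\n"
        index = ChainIndex.from_file(_write_chain(tmp_path, text))
        whole = _iv("tA", 100, 900)
        parts = [_iv("tA", 100, 450), _iv("tA", 450, 900)]
        whole_fraction = lift_interval(whole, index, min_match=0.01).matched_fraction
        weighted = sum(
            lift_interval(p, index, min_match=0.01).matched_fraction * p.length
            for p in parts
        ) / whole.length
        assert weighted == pytest.approx(whole_fraction)


class TestOracleAgreement:
    def test_random_intervals_against_generated_chains(self, tmp_path):
        rng = np.random.default_rng(20260930)
        t_size = 20_000
        disagreements = 0
        n_checked = 0
        for i in range(10):
            n_edits = int(rng.integers(0, 6))
            edits, pos = [], 0
            for _ in range(n_edits):
                pos += int(rng.integers(100, 3000))
                if pos >= t_size - 200:
                    break
                edits.append((pos, int(rng.integers(0, 150)), int(rng.integers(0, 150))))
                pos += edits[-1][1]
            text = generate_chain({"tA": t_size}, edits={"tA": edits})
            path = _write_chain(tmp_path, text, name=f"c{i}.chain")
            chains = read_chain(path)
            index = ChainIndex(chains)
            for _ in range(100):
                start = int(rng.integers(0, t_size - 1))
                end = start + int(rng.integers(1, 2000))
                iv = _iv("tA", start, min(end, t_size))
                mine = lift_interval(iv, index)
                status, coords, fraction = brute_force_lift(iv, chains)
                n_checked += 1
                if mine.status != status or abs(mine.matched_fraction - fraction) > 1e-12:
                    disagreements += 1
                elif status == "mapped":
                    got = (mine.mapped_interval.chrom, mine.mapped_interval.start,
                           mine.mapped_interval.end)
                    if got != coords:
                        disagreements += 1
        assert n_checked == 1000
        assert disagreements == 0
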