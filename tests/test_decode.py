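"""Decoder: q-filter, alignment oracle, addressing, observation
extraction, two-stage classification, streaming decode and bootstrap."""

import numpy as np
import pytest

from dmos import decode, ldpc, simulate, tape
from dmos.decode import (
    DomainObservation,
    KmerIndex,
    assign_read,
    bootstrap_recovery,
    decode_stream,
    extract_observations,
    filter_reads,
    smith_waterman,
    stage1_classify,
    stage2_bayes,
)
from dmos.ldpc import Message, ldpc_encode, pack_payload, raw_bits_to_plan
from dmos.simulate import (
    NOISELESS,
    MutationModel,
    SignatureProfile,
    SimulatedRead,
    fit_signature_profile,
    make_training_reads,
    sample_reads,
)

BASES = "ACGT"


def make_read(seq, q=30, read_id="r", address=-1):
    return SimulatedRead(read_id=read_id, seq=seq,
                         quals=np.full(len(seq), q),
                         truth_address=address,
                         truth_states=np.zeros(16, dtype=np.uint8),
                         truth_molecule_mutations=[])


def sw_oracle(a, b, match=2.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0):
    """Exhaustive affine-gap local-alignment DP (Gotoh), no pruning.

    Independent of the production implementation; returns the best score.
    A gap of length L scores gap_open + (L-1)*gap_extend.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestQualityFilter:
    def test_high_quality_passes_and_zero_threshold_keeps_all(self):
        reads = [make_read("ACGT" * 10, q=q, read_id=str(q)) for q in (5, 9, 30)]
        assert len(filter_reads(reads, 0.0)) == 3
        kept = filter_reads(reads, 9.0)
        assert [r.read_id for r in kept] == ["9", "30"]

    def test_mean_quality_straddling_threshold(self):
        quals = np.array([8, 9, 10, 11])  # mean 9.5
        read = SimulatedRead("x", "ACGT", quals, -1,
                             np.zeros(16, dtype=np.uint8), [])
        assert filter_reads([read], 9.0) == [read]
        assert filter_reads([read], 9.6) == []

    def test_malformed_fastq_raises(self, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\n+\nII\n")  # quality length mismatch
        with pytest.raises(ValueError, match="FASTQ"):
            decode.parse_fastq(bad)


class TestSmithWaterman:
    def test_identical_23mers(self):
        seq = "AATCAAAATCAAAAAAAAAATGG"
        res = smith_waterman(seq, seq)
        assert res.score == 46
        assert res.a_interval == (0, 23) and res.b_interval == (0, 23)

    def test_no_common_letters_scores_zero(self):
        res = smith_waterman("AAAA", "TTTT")
        assert res.score == 0
        assert res.pairs == []

    def test_matches_exhaustive_dp_oracle(self):
        """200 random pairs (len <= 50) against the independent Gotoh DP."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            la, lb = rng.integers(1, 51, size=2)
            a = "".join(rng.choice(list(BASES), la))
            b = "".join(rng.choice(list(BASES), lb))
            assert smith_waterman(a, b).score == pytest.approx(sw_oracle(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")


class TestAddressing:
    def test_error_free_full_read(self, block):
        reg = block.register(12)
        read = make_read(reg.sequence, address=12)
        hit = assign_read(read, block, KmerIndex(block))
        assert hit is not None and hit.register_address == 12
        assert hit.strand == "+"
        assert len(hit.slot_windows) == 16

    def test_reverse_strand_read(self, block):
        reg = block.register(5)
        read = make_read(tape.revcomp(reg.sequence), address=5)
        hit = assign_read(read, block, KmerIndex(block))
        assert hit is not None and hit.register_address == 5
        assert hit.strand == "-"

    def test_noisy_reads_mostly_correct(self, block):
        """>= 95 % of assigned full-length reads carry the right address
        under default channel noise (high-entropy scheme)."""
        reads = sample_reads(block, ldpc.MutationPlan([], block.block_id),
                             400, rng=31)
        index = KmerIndex(block)
        n_ok = n_assigned = 0
        for read in reads:
            hit = assign_read(read, block, index)
            if hit is None:
                continue
            n_assigned += 1
            n_ok += hit.register_address == read.truth_address
        assert n_assigned > 300
        assert n_ok / n_assigned >= 0.95

    def test_high_entropy_beats_lexicographic(self, block, lex_block):
        """Mis-addressing is rarer under high-entropy permutations."""
        def misrate(b, seed):
            reads = sample_reads(b, ldpc.MutationPlan([], b.block_id), 400, rng=seed)
            index = KmerIndex(b)
            wrong = total = 0
            for read in reads:
                hit = assign_read(read, b, index)
                if hit is None:
                    continue
                total += 1
                wrong += hit.register_address != read.truth_address
            return wrong / total
        assert misrate(block, 32) <= misrate(lex_block, 32)


class TestExtraction:
    def _hit_for(self, block, address, seq=None):
        reg = block.register(address)
        read = make_read(seq or reg.sequence, address=address)
        hit = assign_read(read, block, KmerIndex(block))
        assert hit is not None
        return read, hit

    def test_unmutated_register_all_sites_C(self, mini_block):
        read, hit = self._hit_for(mini_block, 0)
        obs = extract_observations(read, hit, mini_block)
        assert len(obs) == 16
        for o in obs:
            assert set(o.site_states.values()) == {"C"}
            assert o.n_sites_observed == len(
                mini_block.domains[o.domain_id].hotspot_sites)

    def test_fully_mutated_register_all_sites_T(self, mini_block, rng):
        reg = mini_block.register(1)
        model = MutationModel(p_site_on=1.0, p_site_off=0.0, pam_proximal_factor=1.0)
        mol = simulate.apply_writer(reg, np.ones(16, dtype=np.uint8), model, rng,
                                    mini_block.domains)
        read, hit = self._hit_for(mini_block, 1, seq=mol)
        for o in extract_observations(read, hit, mini_block):
            assert set(o.site_states.values()) == {"T"}

    def test_site_under_deletion_recorded_absent(self, mini_block):
        reg = mini_block.register(0)
        dom = mini_block.domains[reg.permutation[0]]
        site = dom.hotspot_sites[0]
        pos = 40 + site  # slot 0 state section offset
        seq = reg.sequence[:pos] + reg.sequence[pos + 1:]
        read, hit = self._hit_for(mini_block, 0, seq=seq)
        o = next(o for o in extract_observations(read, hit, mini_block)
                 if o.slot == 0)
        full = len(dom.hotspot_sites)
        assert o.n_sites_observed == full - 1
        assert o.site_states.get(site) != "C"


def flat_profile(value_on=0.8, value_off=0.01, t_low=0.1, t_high=0.5):
    domains = tape.default_domains()
    p1, p0 = {}, {}
    for d in domains:
        for s in d.hotspot_sites:
            p1[(d.domain_id, s)] = value_on
            p0[(d.domain_id, s)] = value_off
    return SignatureProfile(p1=p1, p0=p0,
                            t_low={i: t_low for i in range(16)},
                            t_high={i: t_high for i in range(16)})


class TestClassification:
    def test_stage1_rules(self):
        assert stage1_classify(0.9, 10, 0.1, 0.5) == 1
        assert stage1_classify(0.05, 10, 0.1, 0.5) == 0
        assert stage1_classify(0.5, 10, 0.1, 0.5) == decode.UNCERTAIN  # boundary
        assert stage1_classify(0.1, 10, 0.1, 0.5) == decode.UNCERTAIN
        assert stage1_classify(0.9, 3, 0.1, 0.5) == decode.UNCERTAIN  # few reads

    def test_stage2_degenerate_likelihood(self):
        profile = flat_profile(value_on=1 - 1e-9, value_off=1e-9)
        dom = tape.default_domains()[0]
        obs = DomainObservation("r", 0, 0, 0,
                                {s: "T" for s in dom.hotspot_sites},
                                len(dom.hotspot_sites))
        posterior, call = stage2_bayes([obs], profile)
        assert posterior == pytest.approx(1.0)
        assert call == 1

    def test_stage2_symmetric_profile_balanced_evidence(self):
        profile = flat_profile(value_on=0.7, value_off=0.3)
        dom = tape.default_domains()[0]
        s0, s1 = dom.hotspot_sites[:2]
        obs = DomainObservation("r", 0, 0, 0, {s0: "T", s1: "C"}, 2)
        posterior, call = stage2_bayes([obs], profile)
        assert posterior == pytest.approx(0.5)
        assert call == decode.UNCALLED

    def test_stage2_empty_uncalled(self):
        posterior, call = stage2_bayes([], flat_profile())
        assert call == decode.UNCALLED

    def test_stage2_beats_stage1_on_uncertain_bits(self, mini_block):
        """Bits with too few reads for stage 1 are still mostly recovered
        by the per-read likelihood model."""
        rng = np.random.default_rng(41)
        model = MutationModel()
        reads, conds = make_training_reads(mini_block, 300, model, rng=42)
        profile = fit_signature_profile(reads, conds, mini_block, rng=42)
        # single-read observations: stage 1 cannot call them (min reads), a
        # posteriori stage 2 should get most right
        bits = rng.integers(0, 2, size=200)
        correct = 0
        called = 0
        for truth in bits:
            plan_states = np.zeros(16, dtype=np.uint8)
            plan_states[0] = truth
            reg = mini_block.register(0)
            mol = simulate.apply_writer(reg, plan_states, model, rng,
                                        mini_block.domains)
            read = make_read(mol, address=0)
            obs = decode.observations_from_truth(read, mini_block)
            obs0 = [o for o in obs if o.slot == 0]
            posterior, call = stage2_bayes(obs0, profile, delta=0.3)
            if call != decode.UNCALLED:
                called += 1
                correct += call == truth
        assert called > 100
        assert correct / called > 0.9


@pytest.fixture(scope="module")
def mini_profile(mini_block):
    tr, conds = make_training_reads(mini_block, 300, MutationModel(), rng=52)
    return fit_signature_profile(tr, conds, mini_block, rng=52)


class TestStreamingDecode:
    def test_snapshot_cadence(self, mini_profile, default_code, block):
        """One snapshot per 100 reads plus a final partial one."""
        profile = mini_profile
        reads = sample_reads(block, ldpc.MutationPlan([], block.block_id),
                             250, rng=53)
        _, snaps, _ = decode_stream(reads, block, default_code, profile)
        assert [s.n_reads_processed for s in snaps] == [100, 200, 250]

    def test_noiseless_full_depth_recovery(self, block, default_code):
        payload = np.random.default_rng(54).integers(0, 256, 72,
                                                     dtype=np.uint8).tobytes()
        msg = pack_payload(payload, default_code)[0]
        cw = ldpc_encode(msg, default_code)
        plan = ldpc.codeword_to_plan(cw, block)
        model = MutationModel(p_site_on=1.0, p_site_off=0.0)
        reads = sample_reads(block, plan, 960, model, NOISELESS, rng=55)
        tr, conds = make_training_reads(block, 200, model, NOISELESS, rng=56)
        profile = fit_signature_profile(tr, conds, block, rng=56)
        truth_bits = ldpc.plan_to_bits(plan, block, default_code.n)
        message, snaps, table = decode_stream(
            reads, block, default_code, profile,
            truth_bits=truth_bits, truth_message=msg.bits)
        assert snaps[-1].payload_recovered
        assert snaps[-1].fraction_bits_correct == 1.0
        assert ldpc.unpack_messages(
            [Message(message.bits, len(payload))]) == payload

    def test_fraction_called_non_decreasing(self, mini_profile, default_code, block):
        profile = mini_profile
        reads = sample_reads(block, ldpc.MutationPlan([], block.block_id),
                             400, rng=57)
        _, snaps, _ = decode_stream(reads, block, default_code, profile)
        called = [s.fraction_bits_called for s in snaps]
        assert all(b >= a - 0.05 for a, b in zip(called, called[1:]))


class TestBootstrap:
    def test_noiseless_sd_zero_at_full_depth(self, mini_block):
        bits = np.zeros(64, dtype=np.uint8)
        bits[::3] = 1
        plan = raw_bits_to_plan(bits, mini_block)
        model = MutationModel(p_site_on=1.0, p_site_off=0.0)
        reads = sample_reads(mini_block, plan, 200, model, NOISELESS, rng=61)
        tr, conds = make_training_reads(mini_block, 150, model, NOISELESS, rng=62)
        profile = fit_signature_profile(tr, conds, mini_block, rng=62)
        table = bootstrap_recovery(
            reads, mini_block, _FixedNCode(64), profile,
            truth_bits=bits, n_boot=20, depth_grid=[200], seed=63)
        assert table.sd_fraction_correct.iloc[0] == 0.0
        assert table.mean_fraction_correct.iloc[0] == 1.0

    def test_default_replicates_and_monotone_mean(self, mini_block):
        bits = np.unpackbits(np.frombuffer(b"bootstrp", dtype=np.uint8))[:64]
        plan = raw_bits_to_plan(bits, mini_block)
        reads = sample_reads(mini_block, plan, 300, rng=64)
        tr, conds = make_training_reads(mini_block, 200, rng=65)
        profile = fit_signature_profile(tr, conds, mini_block, rng=65)
        table = bootstrap_recovery(reads, mini_block, _FixedNCode(64), profile,
                                   truth_bits=bits,
                                   depth_grid=[30, 100, 300], seed=66)
        assert (table.n_boot == 250).all()
        called = table.mean_fraction_called.to_numpy()
        assert np.all(np.diff(called) >= -0.02)

    def test_requires_two_replicates(self, mini_block):
        with pytest.raises(ValueError):
            bootstrap_recovery([], mini_block, _FixedNCode(16),
                               flat_profile(), n_boot=1)


class _FixedNCode:
    """Minimal stand-in exposing only the bit count (uncoded bitmap path)."""

    def __init__(self, n):
        self.n = n
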