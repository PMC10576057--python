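"""Read decoding: FASTQ -> addresses -> bit calls -> LDPC -> payload.

Pipeline stages, in the order a read stream is consumed:

1. quality filter (mean q-score threshold);
2. domain location by 12-mer anchoring against the domain index
   sequences, with Smith-Waterman confirmation of each located index
   (both strands tried);
3. domain-calling: the observed (slot, domain) order is matched against
   every register permutation of the block, best positional agreement
   wins, ties go to UNADDRESSED;
4. per-slot observation extraction: the 23-bp reference state section is
   locally aligned into a window around its anchored position and the
   hotspot-site columns are read off as C (unmutated), T (mutated) or
   absent;
5. two-stage bit classification: per-bit pooled mutated fraction against
   the fitted per-domain thresholds (stage 1), with near-threshold bits
   routed to a per-read Bernoulli likelihood model of the domain's
   mutational signature (stage 2);
6. LLR construction and LDPC decoding, with a streaming snapshot every
   100 reads, plus bootstrap recovery analysis over resampled streams.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from . import ldpc as _ldpc
from .ldpc import LDPCCode, Message, ldpc_decode
from .simulate import SignatureProfile, SimulatedRead
from .tape import DOMAIN_LEN, INDEX_LEN, N_DOMAINS, TapeBlock, revcomp

logger = logging.getLogger(__name__)

UNCERTAIN = "UNCERTAIN"
UNCALLED = "UNCALLED"

#: default decoder tunables
MIN_MEAN_Q = 9.0
MIN_READS_PER_BIT = 5
DELTA = 0.1          # stage-2 posterior margin for a confident call
LLR_CAP = 4.0
SNAPSHOT_INTERVAL = 100
KMER = 12
MIN_KMER_VOTES = 3
INDEX_MIN_SCORE = 40  # SW score to confirm a located 40-bp index
STATE_MIN_SCORE = 24  # SW score to trust a state-section alignment
WINDOW_PAD = 12


# ---------------------------------------------------------------------------
# FASTQ input and quality filtering
# ---------------------------------------------------------------------------

def parse_fastq(path) -> list[SimulatedRead]:
    """Read a FASTQ file into read records (truth fields unset)."""
    reads = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            reads.append(
                SimulatedRead(
                    read_id=rec.id,
                    seq=str(rec.seq),
                    quals=np.asarray(rec.letter_annotations["phred_quality"]),
                    truth_address=-1,
                    truth_states=np.zeros(N_DOMAINS, dtype=np.uint8),
                    truth_molecule_mutations=[],
                )
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record ~{len(reads)} in {path}: {exc}") from exc
    return reads


def filter_reads(reads: list[SimulatedRead], min_mean_q: float = MIN_MEAN_Q):
    kept = [r for r in reads if len(r.quals) and float(np.mean(r.quals)) >= min_mean_q]
    logger.info("q-filter: kept %d of %d reads (min mean q %.1f)",
                len(kept), len(reads), min_mean_q)
    return kept


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SWScoring:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -2.0     # score of the first base of a gap
    gap_extend: float = -1.0   # each further gapped base


@dataclass
class SWResult:
    score: float
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    pairs: list[tuple[int, int]]  # aligned (a_pos, b_pos) matches/mismatches


def _aligner(scoring: SWScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


_DEFAULT_SCORING = SWScoring()
_DEFAULT_ALIGNER = _aligner(_DEFAULT_SCORING)


def smith_waterman(a: str, b: str, scoring: SWScoring | None = None) -> SWResult:
    """Optimal local alignment under affine-gap scoring.

    A gap of length L scores gap_open + (L-1)*gap_extend.  Returns the
    first optimal alignment of the engine's deterministic enumeration
    order; a best score of 0 yields an empty alignment.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    al = _DEFAULT_ALIGNER if scoring is None else _aligner(scoring)
    score = al.score(a, b)
    if score <= 0:
        return SWResult(score=0.0, a_interval=(0, 0), b_interval=(0, 0), pairs=[])
    aln = al.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    pairs = []
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return SWResult(
        score=float(score),
        a_interval=(int(blocks_a[0][0]), int(blocks_a[-1][1])),
        b_interval=(int(blocks_b[0][0]), int(blocks_b[-1][1])),
        pairs=pairs,
    )


def sw_score(a: str, b: str, scoring: SWScoring | None = None) -> float:
    al = _DEFAULT_ALIGNER if scoring is None else _aligner(scoring)
    return float(al.score(a, b))


# ---------------------------------------------------------------------------
# k-mer anchoring of domain index sequences
# ---------------------------------------------------------------------------

class KmerIndex:
    """12-mer lookup from the 16 domain index sequences of a block."""

    def __init__(self, block: TapeBlock, k: int = KMER):
        self.k = k
        self.lut: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for dom in block.domains:
            for off in range(INDEX_LEN - k + 1):
                self.lut[dom.index_seq[off: off + k]].append((dom.domain_id, off))

    def scan(self, seq: str, min_votes: int = MIN_KMER_VOTES):
        """Locate domains: returns [(anchor_pos, domain_id, votes)] sorted.

        anchor_pos estimates where the domain's index starts in the read.
        """
        k = self.k
        votes: dict[int, list[int]] = defaultdict(list)
        lut = self.lut
        for pos in range(len(seq) - k + 1):
            for did, off in lut.get(seq[pos: pos + k], ()):
                votes[did].append(pos - off)
        out = []
        for did, anchors in votes.items():
            if len(anchors) < min_votes:
                continue
            anchors = np.array(anchors)
            med = int(np.median(anchors))
            close = anchors[np.abs(anchors - med) <= 8]
            if len(close) < min_votes:
                continue
            out.append((int(np.median(close)), did, len(close)))
        out.sort()
        return out


@dataclass
class AlignmentHit:
    """Where a read landed: candidate register plus per-slot windows."""

    read_id: str
    register_address: int
    score: float                       # positional agreement count
    strand: str                        # "+" or "-"
    oriented_seq: str                  # read sequence in reference orientation
    slot_windows: dict[int, tuple[int, int]] = field(default_factory=dict)
    slot_domains: dict[int, int] = field(default_factory=dict)


def _slots_from_anchors(dets: list[tuple[int, int, int]]) -> list[int]:
    """Relative slot of each detection from cumulative anchor spacing."""
    rel = [0]
    for i in range(1, len(dets)):
        step = round((dets[i][0] - dets[i - 1][0]) / DOMAIN_LEN)
        rel.append(rel[-1] + max(1, int(step)))
    return rel


def assign_read(
    read: SimulatedRead,
    block: TapeBlock,
    index: KmerIndex,
    min_agree: int = 9,
    min_votes: int = MIN_KMER_VOTES,
    confirm_index: bool = True,
    index_min_score: float = INDEX_MIN_SCORE,
) -> AlignmentHit | None:
    """Domain-call a read to a register address (or None when unaddressed).

    The forward orientation is tried first; the reverse complement is
    used when it anchors more domains.  Truncated reads are handled by
    sliding the observed relative slots over all feasible offsets.
    """
    perms = block.permutation_matrix()
    best = None
    for strand in ("+", "-"):
        seq = read.seq if strand == "+" else revcomp(read.seq)
        dets = index.scan(seq, min_votes)
        if confirm_index and dets:
            confirmed = []
            for anchor, did, votes in dets:
                w0 = max(0, anchor - WINDOW_PAD)
                w1 = min(len(seq), anchor + INDEX_LEN + WINDOW_PAD)
                if w1 - w0 < index.k:
                    continue
                if sw_score(block.domains[did].index_seq, seq[w0:w1]) >= index_min_score:
                    confirmed.append((anchor, did, votes))
            dets = confirmed
        if len(dets) < 2:
            continue
        rel = _slots_from_anchors(dets)
        span = rel[-1]
        dids = np.array([d for _, d, _ in dets])
        for offset in range(0, N_DOMAINS - span):
            slots = np.array(rel) + offset
            if slots.max() >= N_DOMAINS:
                continue
            # drop duplicate slots (chimeric anchors) conservatively
            if len(set(slots.tolist())) != len(slots):
                continue
            agree = (perms[:, slots] == dids[None, :]).sum(axis=1)
            top = int(agree.max())
            winners = np.flatnonzero(agree == top)
            if top < min_agree or len(winners) != 1:
                continue
            cand = AlignmentHit(
                read_id=read.read_id,
                register_address=int(winners[0]),
                score=top,
                strand=strand,
                oriented_seq=seq,
            )
            perm = block.register(cand.register_address).permutation
            for (anchor, did, _v), slot in zip(dets, slots):
                if perm[slot] != did:
                    continue  # disagreeing anchor: do not extract from it
                s0 = max(0, anchor + INDEX_LEN - WINDOW_PAD)
                s1 = min(len(seq), anchor + DOMAIN_LEN + WINDOW_PAD)
                cand.slot_windows[slot] = (s0, s1)
                cand.slot_domains[slot] = did
            if best is None or cand.score > best.score:
                best = cand
    return best


# ---------------------------------------------------------------------------
# observation extraction
# ---------------------------------------------------------------------------

@dataclass
class DomainObservation:
    read_id: str
    register_address: int
    slot: int
    domain_id: int
    site_states: dict[int, str]   # hotspot site -> "C" | "T" | "other"
    n_sites_observed: int

    def mutated_fraction(self) -> float:
        n_t = sum(1 for s in self.site_states.values() if s == "T")
        n_c = sum(1 for s in self.site_states.values() if s == "C")
        return n_t / (n_t + n_c) if (n_t + n_c) else 0.0


def extract_observations(
    read: SimulatedRead,
    hit: AlignmentHit,
    block: TapeBlock,
    state_min_score: float = STATE_MIN_SCORE,
) -> list[DomainObservation]:
    """Per located slot, align the reference state section and read off
    the hotspot-site columns; sites under gaps are recorded absent."""
    out = []
    seq = hit.oriented_seq
    for slot, (w0, w1) in hit.slot_windows.items():
        did = hit.slot_domains[slot]
        dom = block.domains[did]
        window = seq[w0:w1]
        if not window:
            continue
        res = smith_waterman(dom.state_seq, window)
        if res.score < state_min_score:
            continue
        by_ref = dict(res.pairs)
        site_states: dict[int, str] = {}
        n_obs = 0
        for site in dom.hotspot_sites:
            bpos = by_ref.get(site)
            if bpos is None:
                continue
            base = window[bpos]
            if base == "C":
                site_states[site] = "C"
                n_obs += 1
            elif base == "T":
                site_states[site] = "T"
                n_obs += 1
            else:
                site_states[site] = "other"
        out.append(
            DomainObservation(
                read_id=read.read_id,
                register_address=hit.register_address,
                slot=slot,
                domain_id=did,
                site_states=site_states,
                n_sites_observed=n_obs,
            )
        )
    return out


def observations_from_truth(read: SimulatedRead, block: TapeBlock,
                            index: KmerIndex | None = None) -> list[DomainObservation]:
    """Extraction using the known true address (training / calibration)."""
    if index is None:
        index = _block_index(block)
    perm = block.register(read.truth_address).permutation
    for strand in ("+", "-"):
        seq = read.seq if strand == "+" else revcomp(read.seq)
        dets = index.scan(seq)
        if len(dets) < 2:
            continue
        hit = AlignmentHit(
            read_id=read.read_id, register_address=read.truth_address,
            score=len(dets), strand=strand, oriented_seq=seq,
        )
        pos_of = {d: i for i, d in enumerate(perm)}
        ok = 0
        for anchor, did, _v in dets:
            slot = pos_of[did]
            s0 = max(0, anchor + INDEX_LEN - WINDOW_PAD)
            s1 = min(len(seq), anchor + DOMAIN_LEN + WINDOW_PAD)
            hit.slot_windows[slot] = (s0, s1)
            hit.slot_domains[slot] = did
            ok += 1
        if ok >= 2:
            return extract_observations(read, hit, block)
    return []


_INDEX_CACHE: dict[int, KmerIndex] = {}


def _block_index(block: TapeBlock) -> KmerIndex:
    key = id(block)
    if key not in _INDEX_CACHE:
        _INDEX_CACHE.clear()
        _INDEX_CACHE[key] = KmerIndex(block)
    return _INDEX_CACHE[key]


# ---------------------------------------------------------------------------
# two-stage bit classification
# ---------------------------------------------------------------------------

def stage1_classify(
    fraction: float, n_reads: int, t_low: float, t_high: float,
    min_reads_per_bit: int = MIN_READS_PER_BIT,
) -> str | int:
    """Threshold call: 1 above T_high, 0 below T_low, else UNCERTAIN.

    Boundary values are deliberately uncertain — near-threshold bits go
    to the stage-2 likelihood model."""
    if n_reads < min_reads_per_bit:
        return UNCERTAIN
    if fraction > t_high:
        return 1
    if fraction < t_low:
        return 0
    return UNCERTAIN


def observation_log_odds(obs: DomainObservation, profile: SignatureProfile) -> float:
    """log P(sites | state=1) - log P(sites | state=0) for one read's domain."""
    lo = 0.0
    for site, state in obs.site_states.items():
        key = (obs.domain_id, site)
        p1 = profile.p1.get(key)
        p0 = profile.p0.get(key)
        if p1 is None or state == "other":
            continue
        p1 = min(max(p1, 1e-6), 1 - 1e-6)
        p0 = min(max(p0, 1e-6), 1 - 1e-6)
        if state == "T":
            lo += math.log(p1 / p0)
        else:
            lo += math.log((1 - p1) / (1 - p0))
    return lo


def stage2_bayes(
    observations: list[DomainObservation],
    profile: SignatureProfile,
    delta: float = DELTA,
) -> tuple[float, str | int]:
    """Posterior P(state=1) from the summed per-read log-odds, prior 0.5."""
    if not observations:
        return 0.5, UNCALLED
    total = sum(observation_log_odds(o, profile) for o in observations)
    posterior = 1.0 / (1.0 + math.exp(-np.clip(total, -500, 500)))
    if posterior > 1 - delta:
        return posterior, 1
    if posterior < delta:
        return posterior, 0
    return posterior, UNCALLED


# ---------------------------------------------------------------------------
# per-bit accumulation and vectorised classification
# ---------------------------------------------------------------------------

class BitAccumulator:
    """Streaming per-bit sufficient statistics for both classifier stages."""

    def __init__(self, n_bits: int, block: TapeBlock, profile: SignatureProfile,
                 start_register: int = 0):
        self.n_bits = n_bits
        self.block = block
        self.profile = profile
        self.start_register = start_register
        self.n_reads = np.zeros(n_bits, dtype=np.int64)
        self.n_t = np.zeros(n_bits, dtype=np.int64)
        self.n_c = np.zeros(n_bits, dtype=np.int64)
        self.log_odds = np.zeros(n_bits)
        self.domain_of_bit = np.array([
            block.register(start_register + i // N_DOMAINS).permutation[i % N_DOMAINS]
            for i in range(n_bits)
        ])

    def bit_index(self, address: int, slot: int) -> int:
        return (address - self.start_register) * N_DOMAINS + slot

    def add(self, obs: DomainObservation) -> None:
        i = self.bit_index(obs.register_address, obs.slot)
        if not 0 <= i < self.n_bits:
            return
        n_t = sum(1 for s in obs.site_states.values() if s == "T")
        n_c = sum(1 for s in obs.site_states.values() if s == "C")
        if n_t + n_c == 0:
            return
        self.n_reads[i] += 1
        self.n_t[i] += n_t
        self.n_c[i] += n_c
        self.log_odds[i] += observation_log_odds(obs, self.profile)

    def classify(self, min_reads_per_bit: int = MIN_READS_PER_BIT,
                 delta: float = DELTA, llr_cap: float = LLR_CAP) -> pd.DataFrame:
        return classify_bits(
            self.n_reads, self.n_t, self.n_c, self.log_odds, self.domain_of_bit,
            self.profile, min_reads_per_bit=min_reads_per_bit, delta=delta,
            llr_cap=llr_cap,
        )


def classify_bits(
    n_reads: np.ndarray,
    n_t: np.ndarray,
    n_c: np.ndarray,
    log_odds: np.ndarray,
    domain_of_bit: np.ndarray,
    profile: SignatureProfile,
    min_reads_per_bit: int = MIN_READS_PER_BIT,
    delta: float = DELTA,
    llr_cap: float = LLR_CAP,
) -> pd.DataFrame:
    """Vectorised two-stage classification of all bits; returns the call table."""
    n_bits = len(n_reads)
    sites = n_t + n_c
    frac = np.divide(n_t, sites, out=np.zeros(n_bits), where=sites > 0)
    t_low = np.array([profile.t_low[d] for d in domain_of_bit])
    t_high = np.array([profile.t_high[d] for d in domain_of_bit])
    enough = n_reads >= min_reads_per_bit
    s1_one = enough & (frac > t_high)
    s1_zero = enough & (frac < t_low)
    uncertain = ~(s1_one | s1_zero)
    posterior = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -500, 500)))
    s2_one = uncertain & (n_reads > 0) & (posterior > 1 - delta)
    s2_zero = uncertain & (n_reads > 0) & (posterior < delta)
    final = np.full(n_bits, UNCALLED, dtype=object)
    final[s1_one | s2_one] = 1
    final[s1_zero | s2_zero] = 0
    llr = np.zeros(n_bits)
    llr[s1_one] = -llr_cap
    llr[s1_zero] = llr_cap
    s2 = s2_one | s2_zero
    llr[s2] = np.clip(-log_odds[s2], -llr_cap, llr_cap)
    stage1 = np.full(n_bits, UNCERTAIN, dtype=object)
    stage1[s1_one] = 1
    stage1[s1_zero] = 0
    return pd.DataFrame({
        "bit": np.arange(n_bits),
        "n_reads": n_reads,
        "mutated_fraction": frac,
        "stage1_call": stage1,
        "stage2_posterior": np.where(uncertain, posterior, np.nan),
        "final_call": final,
        "llr": llr,
    })


# ---------------------------------------------------------------------------
# streaming decode and bootstrap
# ---------------------------------------------------------------------------

@dataclass
class RecoverySnapshot:
    n_reads_processed: int
    fraction_bits_called: float
    fraction_bits_correct: float | None
    ldpc_converged: bool
    payload_recovered: bool | None


def _snapshot(acc: BitAccumulator, code: LDPCCode, n_processed: int,
              truth_bits: np.ndarray | None, truth_message: np.ndarray | None,
              min_reads_per_bit: int, delta: float, llr_cap: float,
              max_iters: int) -> tuple[RecoverySnapshot, pd.DataFrame, Message]:
    table = acc.classify(min_reads_per_bit, delta, llr_cap)
    called = table.final_call != UNCALLED
    frac_called = float(called.mean())
    frac_correct = None
    if truth_bits is not None and called.any():
        calls = table.final_call[called].to_numpy().astype(int)
        frac_correct = float((calls == truth_bits[called.to_numpy()]).mean())
    erase_frac = float((table.llr == 0).mean())
    message, converged, _ = ldpc_decode(
        table.llr.to_numpy(), code, max_iters=max_iters,
        postprocess="auto" if erase_frac <= 0.15 else "never",
    )
    recovered = None
    if truth_message is not None:
        recovered = bool(converged and np.array_equal(message.bits, truth_message))
    elif converged:
        recovered = True
    snap = RecoverySnapshot(
        n_reads_processed=n_processed,
        fraction_bits_called=frac_called,
        fraction_bits_correct=frac_correct,
        ldpc_converged=bool(converged),
        payload_recovered=recovered,
    )
    return snap, table, message


def decode_stream(
    reads: list[SimulatedRead],
    block: TapeBlock,
    code: LDPCCode,
    profile: SignatureProfile,
    truth_bits: np.ndarray | None = None,
    truth_message: np.ndarray | None = None,
    start_register: int = 0,
    snapshot_interval: int = SNAPSHOT_INTERVAL,
    min_mean_q: float = MIN_MEAN_Q,
    min_agree: int = 9,
    min_reads_per_bit: int = MIN_READS_PER_BIT,
    delta: float = DELTA,
    llr_cap: float = LLR_CAP,
    max_iters: int = _ldpc.MAX_ITERS,
    stop_on_recovery: bool = False,
) -> tuple[Message, list[RecoverySnapshot], pd.DataFrame]:
    """Consume reads in order, snapshotting the decoder state every
    ``snapshot_interval`` reads; returns the final decoded message, the
    snapshot list and the final bit-call table."""
    index = _block_index(block)
    acc = BitAccumulator(code.n, block, profile, start_register)
    snapshots: list[RecoverySnapshot] = []
    message = None
    table = None
    n_processed = 0
    for read in reads:
        n_processed += 1
        if len(read.quals) and float(np.mean(read.quals)) < min_mean_q:
            pass
        else:
            hit = assign_read(read, block, index, min_agree=min_agree)
            if hit is not None:
                for obs in extract_observations(read, hit, block):
                    acc.add(obs)
        if n_processed % snapshot_interval == 0:
            snap, table, message = _snapshot(
                acc, code, n_processed, truth_bits, truth_message,
                min_reads_per_bit, delta, llr_cap, max_iters)
            snapshots.append(snap)
            if stop_on_recovery and snap.payload_recovered:
                return message, snapshots, table
    if n_processed % snapshot_interval != 0 or not snapshots:
        snap, table, message = _snapshot(
            acc, code, n_processed, truth_bits, truth_message,
            min_reads_per_bit, delta, llr_cap, max_iters)
        snapshots.append(snap)
    return message, snapshots, table


def snapshots_to_frame(snapshots: list[RecoverySnapshot]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in snapshots])


def collect_observations(
    reads: list[SimulatedRead],
    block: TapeBlock,
    min_mean_q: float = MIN_MEAN_Q,
    min_agree: int = 9,
) -> list[tuple[int, list[DomainObservation]]]:
    """Address + extract every read once; used by the bootstrap analysis."""
    index = _block_index(block)
    out = []
    for i, read in enumerate(reads):
        if len(read.quals) and float(np.mean(read.quals)) < min_mean_q:
            out.append((i, []))
            continue
        hit = assign_read(read, block, index, min_agree=min_agree)
        out.append((i, extract_observations(read, hit, block) if hit else []))
    return out


def bootstrap_recovery(
    reads: list[SimulatedRead],
    block: TapeBlock,
    code: LDPCCode,
    profile: SignatureProfile,
    truth_bits: np.ndarray | None = None,
    n_boot: int = 250,
    depth_grid: list[int] | None = None,
    seed: int = 0,
    min_reads_per_bit: int = MIN_READS_PER_BIT,
    delta: float = DELTA,
    llr_cap: float = LLR_CAP,
) -> pd.DataFrame:
    """Bootstrap recovery curves: resample read streams with replacement.

    At each depth on the grid, ``n_boot`` streams of that many reads are
    drawn with replacement from the dataset; the mean and SD of the
    fraction of bits called (and correct, when truth is given) are
    reported."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    per_read = collect_observations(reads, block)
    acc0 = BitAccumulator(code.n, block, profile)
    # flatten observations into parallel arrays for fast resampling
    r_idx, b_idx, o_t, o_c, o_lo = [], [], [], [], []
    for i, obs_list in per_read:
        for obs in obs_list:
            j = acc0.bit_index(obs.register_address, obs.slot)
            if not 0 <= j < code.n:
                continue
            n_t = sum(1 for s in obs.site_states.values() if s == "T")
            n_c = sum(1 for s in obs.site_states.values() if s == "C")
            if n_t + n_c == 0:
                continue
            r_idx.append(i)
            b_idx.append(j)
            o_t.append(n_t)
            o_c.append(n_c)
            o_lo.append(observation_log_odds(obs, profile))
    r_idx = np.array(r_idx, dtype=np.int64)
    b_idx = np.array(b_idx, dtype=np.int64)
    o_t = np.array(o_t, dtype=np.float64)
    o_c = np.array(o_c, dtype=np.float64)
    o_lo = np.array(o_lo)
    n_total = len(reads)
    if depth_grid is None:
        depth_grid = sorted({max(1, n_total // 8), n_total // 4, n_total // 2, n_total})
    rows = []
    for depth in depth_grid:
        called = np.empty(n_boot)
        correct = np.full(n_boot, np.nan)
        for b in range(n_boot):
            w = np.bincount(rng.integers(0, n_total, size=depth), minlength=n_total)
            wr = w[r_idx].astype(np.float64)
            n_reads = np.bincount(b_idx, weights=(wr > 0) * w[r_idx], minlength=code.n)
            n_t = np.bincount(b_idx, weights=wr * o_t, minlength=code.n)
            n_c = np.bincount(b_idx, weights=wr * o_c, minlength=code.n)
            lo = np.bincount(b_idx, weights=wr * o_lo, minlength=code.n)
            table = classify_bits(
                n_reads.astype(np.int64), n_t, n_c, lo, acc0.domain_of_bit,
                profile, min_reads_per_bit, delta, llr_cap)
            mask = table.final_call != UNCALLED
            called[b] = float(mask.mean())
            if truth_bits is not None and mask.any():
                calls = table.final_call[mask].to_numpy().astype(int)
                correct[b] = float((calls == truth_bits[mask.to_numpy()]).mean())
        rows.append({
            "depth": depth,
            "mean_fraction_called": called.mean(),
            "sd_fraction_called": called.std(ddof=1),
            "mean_fraction_correct": np.nanmean(correct) if truth_bits is not None else np.nan,
            "sd_fraction_correct": np.nanstd(correct, ddof=1) if truth_bits is not None else np.nan,
            "n_boot": n_boot,
        })
    return pd.DataFrame(rows)
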