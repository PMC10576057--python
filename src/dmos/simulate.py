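"""Writer chemistry and nanopore read-channel simulation.

The writer model emulates dCas9/APOBEC3A base editing on a register
molecule: in every domain whose bit is set, each dTdCdR-motif cytosine
of the state section deaminates C->T independently; motif cytosines
within ~6 nt of the PAM are strongly suppressed, and untargeted domains
see only a small background conversion rate (editing requires a bound
dCas9, so domains are independent — the orthogonality assumption).

The sequencing channel is a simple per-base substitution/insertion/
deletion model with optional read truncation and synthetic quality
scores; it stands in for a MinION/Flongle run so the decoder can be
exercised without real reads.  Ground truth (address, 16-bit state,
per-molecule conversions) is carried alongside each simulated read.

Default rates are package defaults chosen so that threshold calls are
separable yet imperfect — both classifier stages and the LDPC layer do
real work — not measured chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ldpc import MutationPlan, plan_states
from .tape import (
    DOMAIN_LEN,
    INDEX_LEN,
    N_DOMAINS,
    PAM_PROXIMAL_DIST,
    DomainSpec,
    RegisterSpec,
    TapeBlock,
    pam_distance,
    revcomp,
)


@dataclass(frozen=True)
class MutationModel:
    """Per-site C->T conversion probabilities of the writer reaction."""

    p_site_on: float = 0.8        # targeted hotspot-motif cytosine
    p_site_off: float = 0.005     # background (untargeted domain / non-motif C)
    pam_proximal_factor: float = 0.1  # suppression of motif C's near the PAM
    site_overrides: dict = field(default_factory=dict)  # (domain_id, site) -> p

    def __post_init__(self):
        if not 0 <= self.p_site_off < self.p_site_on <= 1:
            raise ValueError("need 0 <= p_site_off < p_site_on <= 1")
        if not 0 <= self.pam_proximal_factor <= 1:
            raise ValueError("pam_proximal_factor must be in [0,1]")

    def p_on(self, domain_id: int, site: int) -> float:
        p = self.site_overrides.get((domain_id, site), self.p_site_on)
        if pam_distance(site) < PAM_PROXIMAL_DIST:
            p *= self.pam_proximal_factor
        return p


@dataclass(frozen=True)
class SequencingErrorModel:
    """Per-base nanopore-style error channel."""

    p_sub: float = 0.03
    p_ins: float = 0.02
    p_del: float = 0.03
    p_truncate: float = 0.1   # read covers only a contiguous piece of the register
    p_reverse: float = 0.5    # read reported on the reverse strand
    q_mean: float = 12.0
    q_sd: float = 3.0

    def __post_init__(self):
        if min(self.p_sub, self.p_ins, self.p_del) < 0:
            raise ValueError("error rates must be >= 0")
        if self.p_sub + self.p_ins + self.p_del >= 0.5:
            raise ValueError("combined per-base error rate must be < 0.5")


NOISELESS = SequencingErrorModel(p_sub=0, p_ins=0, p_del=0, p_truncate=0, p_reverse=0)


@dataclass
class SimulatedRead:
    read_id: str
    seq: str
    quals: np.ndarray
    truth_address: int
    truth_states: np.ndarray                   # 16 bits, slot order
    truth_molecule_mutations: list[tuple[int, int]]  # (slot, site) conversions


@dataclass
class SignatureProfile:
    """Fitted per-site conversion rates and per-domain stage-1 thresholds."""

    p1: dict        # (domain_id, site) -> P(T | targeted)
    p0: dict        # (domain_id, site) -> P(T | untargeted)
    t_low: dict     # domain_id -> stage-1 lower threshold
    t_high: dict    # domain_id -> stage-1 upper threshold


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def apply_writer(
    register: RegisterSpec,
    states: np.ndarray,
    model: MutationModel,
    rng: np.random.Generator,
    domains: list[DomainSpec],
    spacer_len: int = 0,
    return_mutations: bool = False,
):
    """One written molecule: per-slot independent C->T conversions.

    Slots with state 1 convert their motif cytosines with ``p_site_on``
    (PAM-proximal ones suppressed); slots with state 0 and non-motif
    cytosines convert at the background rate.  Returns the molecule
    sequence (and the (slot, site) conversion list when requested).
    """
    seq = np.frombuffer(register.sequence.encode(), dtype="S1").copy()
    mutations = []
    offset0 = len(register.sequence) - len(domains[0].sequence) * N_DOMAINS \
        - spacer_len * (N_DOMAINS - 1)
    # leading offset only for barcoded registers (forward barcode prefix)
    lead = offset0 // 2 if register.barcode is not None else 0
    for slot in range(N_DOMAINS):
        did = register.permutation[slot]
        dom = domains[did]
        start = lead + slot * (DOMAIN_LEN + spacer_len)
        state_start = start + INDEX_LEN
        targeted = bool(states[slot])
        for site in range(len(dom.state_seq)):
            if dom.state_seq[site] != "C":
                continue
            if targeted and site in dom.motif_sites:
                p = model.p_on(did, site)
            else:
                p = model.p_site_off
            if p > 0 and rng.random() < p:
                seq[state_start + site] = b"T"
                mutations.append((slot, site))
    molecule = seq.tobytes().decode()
    if return_mutations:
        return molecule, mutations
    return molecule


# ---------------------------------------------------------------------------
# sequencing channel
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _channel(seq: str, err: SequencingErrorModel, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    u = rng.random(n)
    keep = u >= err.p_del
    arr = arr[keep]
    u = u[keep]
    sub = u < err.p_del + err.p_sub
    if sub.any():
        arr = arr.copy()
        # substitute with a uniformly random *different* base
        repl = _BASES[rng.integers(0, 4, size=int(sub.sum()))]
        same = repl == arr[sub]
        while same.any():
            repl[same] = _BASES[rng.integers(0, 4, size=int(same.sum()))]
            same = repl == arr[sub]
        arr[sub] = repl
    ins_mask = rng.random(len(arr)) < err.p_ins
    if ins_mask.any():
        pieces = []
        last = 0
        for i in np.flatnonzero(ins_mask):
            pieces.append(arr[last: i + 1])
            pieces.append(_BASES[rng.integers(0, 4, size=1)])
            last = i + 1
        pieces.append(arr[last:])
        arr = np.concatenate(pieces)
    return arr.tobytes().decode()


def _truncate(seq: str, err: SequencingErrorModel, rng: np.random.Generator) -> str:
    if err.p_truncate <= 0 or rng.random() >= err.p_truncate:
        return seq
    n = len(seq)
    start = int(rng.integers(0, max(1, n - DOMAIN_LEN)))
    # geometric length with mean half a register, at least one full domain
    length = DOMAIN_LEN + int(rng.geometric(2.0 / n))
    return seq[start: start + length]


def sample_reads(
    block: TapeBlock,
    plan: MutationPlan,
    n_reads: int,
    mut_model: MutationModel | None = None,
    err_model: SequencingErrorModel | None = None,
    rng: np.random.Generator | int | None = None,
    weights: np.ndarray | None = None,
) -> list[SimulatedRead]:
    """Draw reads uniformly (or weighted) over registers through the channel.

    Each read is a fresh writer molecule -> optional truncation ->
    substitution/indel channel -> quality scores.  Deterministic given
    the RNG seed.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    mut_model = mut_model or MutationModel()
    err_model = err_model or SequencingErrorModel()
    rng = np.random.default_rng(rng)
    states = plan_states(plan, block)
    spacer_len = len(block.spacer)
    if weights is None:
        addresses = rng.integers(0, block.n_registers, size=n_reads)
    else:
        w = np.asarray(weights, dtype=float)
        addresses = rng.choice(block.n_registers, size=n_reads, p=w / w.sum())
    reads = []
    for i, address in enumerate(addresses):
        reg = block.register(int(address))
        st = states[int(address)]
        molecule, muts = apply_writer(
            reg, st, mut_model, rng, block.domains, spacer_len, return_mutations=True
        )
        seq = _truncate(molecule, err_model, rng)
        seq = _channel(seq, err_model, rng)
        if err_model.p_reverse > 0 and rng.random() < err_model.p_reverse:
            seq = revcomp(seq)
        quals = np.clip(
            rng.normal(err_model.q_mean, err_model.q_sd, size=len(seq)), 2, 41
        ).astype(int)
        reads.append(
            SimulatedRead(
                read_id=f"read_{i}",
                seq=seq,
                quals=quals,
                truth_address=int(address),
                truth_states=st.copy(),
                truth_molecule_mutations=muts,
            )
        )
    return reads


def write_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(33 + int(x)) for x in r.quals)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{q}\n")


def write_truth(reads: list[SimulatedRead], path) -> None:
    rows = [
        {
            "read_id": r.read_id,
            "truth_address": r.truth_address,
            "truth_states": "".join(str(int(b)) for b in r.truth_states),
        }
        for r in reads
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"truth_states": str})
    return df


# ---------------------------------------------------------------------------
# training conditions and signature fitting
# ---------------------------------------------------------------------------

def make_training_reads(
    block: TapeBlock,
    n_reads_per_condition: int = 400,
    mut_model: MutationModel | None = None,
    err_model: SequencingErrorModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[SimulatedRead], list[str]]:
    """Reads from the two calibration conditions: all-targeted / none-targeted.

    Mirrors the control conditions of the orthogonality experiments; the
    returned condition labels align with the returned reads.
    """
    rng = np.random.default_rng(rng)
    all_on = MutationPlan(
        entries=[
            (r.address, s, r.permutation[s], 1)
            for r in block.registers
            for s in range(N_DOMAINS)
        ],
        block_id=block.block_id,
    )
    none_on = MutationPlan(entries=[], block_id=block.block_id)
    on_reads = sample_reads(block, all_on, n_reads_per_condition, mut_model,
                            err_model, rng)
    off_reads = sample_reads(block, none_on, n_reads_per_condition, mut_model,
                             err_model, rng)
    for r in off_reads:
        r.read_id = "off_" + r.read_id
    reads = on_reads + off_reads
    conditions = ["targeted"] * len(on_reads) + ["untargeted"] * len(off_reads)
    return reads, conditions


def fit_signature_profile(
    reads: list[SimulatedRead],
    conditions: list[str],
    block: TapeBlock,
    set_size: int = 20,
    n_sets: int = 200,
    rng: np.random.Generator | int | None = None,
) -> SignatureProfile:
    """Estimate per-site conversion rates and stage-1 thresholds.

    Per (domain, site): p1 from the all-targeted condition and p0 from the
    none-targeted condition, each with pseudocount 1.  Thresholds per
    domain: T_low = 99th percentile of the untargeted read-set mutated
    fraction, T_high = 1st percentile of the targeted one (read sets of
    ``set_size`` reads resampled ``n_sets`` times), clamped to
    T_low <= T_high.
    """
    from .decode import observations_from_truth  # local import: decode uses our types

    rng = np.random.default_rng(rng)
    n_dom = len(block.domains)
    per_cond = {"targeted": [], "untargeted": []}
    for read, cond in zip(reads, conditions):
        per_cond[cond].extend(observations_from_truth(read, block))
    missing = []
    for did in range(n_dom):
        for cond in ("targeted", "untargeted"):
            if not any(o.domain_id == did for o in per_cond[cond]):
                missing.append((did, cond))
    if missing:
        raise ValueError(
            "training set lacks conditions for domains: "
            + ", ".join(f"{d}/{c}" for d, c in missing)
        )
    p1, p0 = {}, {}
    t_low, t_high = {}, {}
    for did in range(n_dom):
        dom = block.domains[did]
        for cond, store in (("targeted", p1), ("untargeted", p0)):
            obs = [o for o in per_cond[cond] if o.domain_id == did]
            for site in dom.hotspot_sites:
                n_t = sum(1 for o in obs if o.site_states.get(site) == "T")
                n_obs = sum(1 for o in obs if o.site_states.get(site) in ("C", "T"))
                store[(did, site)] = (n_t + 1) / (n_obs + 2)
        # clamp so the targeted estimate never drops below background
        for site in dom.hotspot_sites:
            if p1[(did, site)] < p0[(did, site)]:
                p1[(did, site)], p0[(did, site)] = p0[(did, site)], p1[(did, site)]
        fracs = {}
        for cond in ("targeted", "untargeted"):
            obs = [o for o in per_cond[cond] if o.domain_id == did]
            per_read = np.array([o.mutated_fraction() for o in obs
                                 if o.n_sites_observed > 0])
            sets = rng.choice(per_read, size=(n_sets, min(set_size, len(per_read))))
            fracs[cond] = sets.mean(axis=1)
        lo = float(np.percentile(fracs["untargeted"], 99))
        hi = float(np.percentile(fracs["targeted"], 1))
        if lo > hi:
            lo = hi = (lo + hi) / 2
        t_low[did], t_high[did] = lo, hi
    return SignatureProfile(p1=p1, p0=p0, t_low=t_low, t_high=t_high)
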