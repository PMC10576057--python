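"""Blank DNA tape model: domains, registers, blocks and addressing.

A *register* is one DNA molecule of the tape, the concatenation of 16
shared *domains* in a register-specific order.  Each domain is a 40-bp
index sequence (a unique locator tag) followed by a 23-bp state section
(20-nt protospacer + 3-nt NGG PAM).  Writing a ``1`` means base-editing
the state section's cytosines; the index order encodes the register's
address ("domain-calling").

Three addressing schemes are supported:

* ``barcode``       — identity domain order, register identity carried by
                      a (forward, reverse) primer barcode pair;
* ``lexicographic`` — the address-th permutation of the 16 domains in
                      lexicographic order;
* ``high_entropy``  — a keyed deterministic shuffle chosen so consecutive
                      addresses get maximally dissimilar orders.

Sequences are stored as the displaced (mutated) strand, so every edit is
a literal C->T on the stored string.  Coordinates are 0-based half-open;
within a state section the protospacer occupies positions 0..20 and the
PAM positions 20..23.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
PURINES = frozenset("AG")

#: length of the gRNA-complementary protospacer within a state section
PROTOSPACER_LEN = 20
#: length of the full state section (protospacer + NGG PAM)
STATE_LEN = 23
#: length of a domain index sequence
INDEX_LEN = 40
#: length of one full domain (index + state)
DOMAIN_LEN = INDEX_LEN + STATE_LEN
#: number of domains (bits) per register
N_DOMAINS = 16
#: cytosines closer than this many nt to the PAM mutate poorly
PAM_PROXIMAL_DIST = 6
#: a valid state sequence needs at least this many hotspot motifs
MIN_HOTSPOT_MOTIFS = 2
#: minimum pairwise edit distance between domain index sequences
MIN_INDEX_DISTANCE = 10

#: sentinel returned when a read's domain order cannot be mapped to an address
UNADDRESSED = -1

SCHEMES = ("barcode", "lexicographic", "high_entropy")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# domain schema and state-sequence validation
# ---------------------------------------------------------------------------

def find_tcr_motifs(state_seq: str) -> list[int]:
    """0-based positions of the C of each dTdCdR motif in the protospacer.

    The motif is T-C-purine; the C must lie inside the protospacer
    (positions 0..20) while the flanking bases may extend into the PAM.
    """
    sites = []
    for p in range(1, min(PROTOSPACER_LEN, len(state_seq) - 1)):
        if state_seq[p] == "C" and state_seq[p - 1] == "T" and state_seq[p + 1] in PURINES:
            sites.append(p)
    return sites


def pam_distance(pos: int) -> int:
    """Distance in nt between a protospacer position and the PAM start."""
    return PROTOSPACER_LEN - pos


def hotspot_filter(sites: list[int]) -> list[int]:
    """Motif sites far enough from the PAM to be efficient APOBEC3A substrates."""
    return [p for p in sites if pam_distance(p) >= PAM_PROXIMAL_DIST]


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    n_motifs: int
    n_hotspot_motifs: int
    failures: list[str]
    motif_sites: list[int] = field(default_factory=list)
    hotspot_sites: list[int] = field(default_factory=list)


def validate_state_sequence(seq: str) -> ValidationReport:
    """Check a candidate state sequence against the tape design rules.

    Rules: 23 bp total, NGG PAM at the 3' end, and at least two dTdCdR
    motif cytosines located >= 6 nt from the PAM (the mutagenic hotspot).
    """
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise ValueError(f"non-ACGT character {ch!r} at position {i}")
    failures = []
    if len(seq) != STATE_LEN:
        failures.append("length")
        motif_sites: list[int] = []
        hotspot_sites: list[int] = []
    else:
        if not (seq[21] == "G" and seq[22] == "G"):
            failures.append("pam")
        motif_sites = find_tcr_motifs(seq)
        hotspot_sites = hotspot_filter(motif_sites)
        if len(hotspot_sites) < MIN_HOTSPOT_MOTIFS:
            failures.append("hotspots")
    return ValidationReport(
        valid=not failures,
        n_motifs=len(motif_sites),
        n_hotspot_motifs=len(hotspot_sites),
        failures=failures,
        motif_sites=motif_sites,
        hotspot_sites=hotspot_sites,
    )


@dataclass(frozen=True)
class DomainSpec:
    """One of the 16 shared tape domains (one bit of every register)."""

    domain_id: int
    state_seq: str
    index_seq: str
    motif_sites: tuple[int, ...]
    hotspot_sites: tuple[int, ...]

    @classmethod
    def from_sequences(cls, domain_id: int, state_seq: str, index_seq: str) -> "DomainSpec":
        report = validate_state_sequence(state_seq)
        if not report.valid:
            raise ValueError(
                f"domain {domain_id}: state sequence fails rules {report.failures}"
            )
        if len(index_seq) != INDEX_LEN:
            raise ValueError(f"domain {domain_id}: index length {len(index_seq)} != {INDEX_LEN}")
        return cls(
            domain_id=domain_id,
            state_seq=state_seq,
            index_seq=index_seq,
            motif_sites=tuple(report.motif_sites),
            hotspot_sites=tuple(report.hotspot_sites),
        )

    @property
    def sequence(self) -> str:
        return self.index_seq + self.state_seq


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (plain DP; index sequences are short)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def default_domains(seed: int = 20230) -> list[DomainSpec]:
    """Deterministically generated 16-domain set satisfying the design rules.

    Stand-in for an experimentally validated set: protospacers carry 2-3
    planted hotspot dTdCdR motifs (and, in half of the domains, one
    PAM-proximal motif so that proximity suppression is observable);
    index sequences are random 40-mers re-drawn until all pairwise edit
    distances are >= 10.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    non_c = np.array(list("AGT"))
    domains: list[DomainSpec] = []
    indexes: list[str] = []
    for did in range(N_DOMAINS):
        while True:
            proto = rng.choice(non_c, size=PROTOSPACER_LEN)
            n_hot = int(rng.integers(2, 4))
            # plant motifs as non-overlapping T-C-R triplets; hotspot C's at
            # protospacer positions <= 14 (>= 6 nt from the PAM)
            c_positions = rng.choice(np.arange(2, 14), size=n_hot, replace=False)
            if np.min(np.diff(np.sort(c_positions))) < 3:
                continue
            positions = list(c_positions)
            if did % 2 == 0:
                positions.append(17)  # PAM-proximal motif, suppressed writer site
            for p in positions:
                proto[p - 1] = "T"
                proto[p] = "C"
                proto[p + 1] = rng.choice(np.array(list("AG")))
            state = "".join(proto) + rng.choice(np.array(list("ACGT"))) + "GG"
            if validate_state_sequence(state).valid:
                break
        while True:
            idx = "".join(rng.choice(bases, size=INDEX_LEN))
            if all(edit_distance(idx, other) >= MIN_INDEX_DISTANCE for other in indexes):
                break
        indexes.append(idx)
        domains.append(DomainSpec.from_sequences(did, state, idx))
    return domains


# ---------------------------------------------------------------------------
# addressing schemes
# ---------------------------------------------------------------------------

def lexicographic_permutation(address: int, n_domains: int) -> list[int]:
    """The ``address``-th permutation of 0..n_domains-1 in lexicographic order."""
    if not 0 <= address < math.factorial(n_domains):
        raise ValueError(f"address {address} out of range for {n_domains}! permutations")
    pool = list(range(n_domains))
    perm = []
    rem = address
    for i in range(n_domains, 0, -1):
        f = math.factorial(i - 1)
        q, rem = divmod(rem, f)
        perm.append(pool.pop(q))
    return perm


def lexicographic_rank(perm: list[int]) -> int:
    """Inverse of :func:`lexicographic_permutation`."""
    pool = sorted(perm)
    rank = 0
    for i, v in enumerate(perm):
        j = pool.index(v)
        rank += j * math.factorial(len(perm) - i - 1)
        pool.pop(j)
    return rank


def high_entropy_permutation(address: int, n_domains: int, key: int = 0) -> list[int]:
    """Deterministic keyed shuffle: same (address, key) -> same permutation.

    Uses a Fisher-Yates shuffle seeded from (key, address), so consecutive
    addresses receive unrelated orders — far more dissimilar than the
    lexicographic scheme, which makes noisy domain-calling less ambiguous.
    """
    if address < 0:
        raise ValueError("address must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([key & 0x7FFFFFFF, address]))
    return [int(x) for x in rng.permutation(n_domains)]


def kendall_tau_distance(p: list[int], q: list[int]) -> int:
    """Number of discordant pairs between two permutations of the same set."""
    pos = {v: i for i, v in enumerate(p)}
    mapped = [pos[v] for v in q]
    n = len(mapped)
    return sum(1 for i in range(n) for j in range(i + 1, n) if mapped[i] > mapped[j])


# ---------------------------------------------------------------------------
# registers and blocks
# ---------------------------------------------------------------------------

def barcode_sequences(n_barcodes: int, seed: int = 77, length: int = 12) -> list[str]:
    """Deterministic primer barcode sequences (one per barcode id)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: list[str] = []
    while len(seqs) < n_barcodes:
        s = "".join(rng.choice(bases, size=length))
        if all(edit_distance(s, t) >= 4 for t in seqs):
            seqs.append(s)
    return seqs


@dataclass(frozen=True)
class BarcodePair:
    fwd_id: int
    rev_id: int
    fwd_seq: str
    rev_seq: str


def barcode_combinations(n_barcodes: int) -> list[BarcodePair]:
    """All ordered (forward, reverse) primer pairs: n_barcodes**2 addresses."""
    if n_barcodes < 1:
        raise ValueError("n_barcodes must be >= 1")
    seqs = barcode_sequences(n_barcodes)
    return [
        BarcodePair(f, r, seqs[f], seqs[r])
        for f in range(n_barcodes)
        for r in range(n_barcodes)
    ]


@dataclass(frozen=True)
class RegisterSpec:
    """One tape molecule: an addressed permutation of the 16 domains."""

    address: int
    permutation: tuple[int, ...]
    sequence: str
    scheme: str
    barcode: BarcodePair | None = None


@dataclass
class TapeBlock:
    """A tape: the full set of addressed registers sharing one domain set."""

    registers: list[RegisterSpec]
    scheme: str
    domains: list[DomainSpec]
    spacer: str = ""
    shuffle_key: int = 0
    block_id: str = "block0"

    @property
    def n_registers(self) -> int:
        return len(self.registers)

    def register(self, address: int) -> RegisterSpec:
        return self.registers[address]

    def permutation_matrix(self) -> np.ndarray:
        """(n_registers, 16) array: row a = domain order of register a."""
        return np.array([r.permutation for r in self.registers], dtype=np.int64)


def assemble_register_sequence(
    permutation: list[int], domains: list[DomainSpec], spacer: str = ""
) -> str:
    parts = []
    for did in permutation:
        parts.append(domains[did].sequence)
    return spacer.join(parts) if spacer else "".join(parts)


def register_slot_interval(slot: int, spacer_len: int = 0) -> tuple[int, int]:
    """Reference interval [start, end) of a slot's domain within a register."""
    start = slot * (DOMAIN_LEN + spacer_len)
    return start, start + DOMAIN_LEN


def build_block(
    n_registers: int = 48,
    scheme: str = "high_entropy",
    domains: list[DomainSpec] | None = None,
    spacer: str = "",
    shuffle_key: int = 0,
    block_id: str = "block0",
) -> TapeBlock:
    """Construct a tape block of addressed registers under one scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if domains is None:
        domains = default_domains()
    n_domains = len(domains)
    barcodes = None
    if scheme == "barcode":
        n_bc = math.isqrt(n_registers - 1) + 1 if n_registers > 1 else 1
        while n_bc * n_bc < n_registers:
            n_bc += 1
        barcodes = barcode_combinations(n_bc)
    registers = []
    seen: set[tuple] = set()
    for address in range(n_registers):
        if scheme == "barcode":
            perm = list(range(n_domains))
            bc = barcodes[address]
        elif scheme == "lexicographic":
            perm = lexicographic_permutation(address, n_domains)
            bc = None
        else:
            perm = high_entropy_permutation(address, n_domains, shuffle_key)
            bc = None
        ident = (bc.fwd_id, bc.rev_id) if bc is not None else tuple(perm)
        if ident in seen:
            raise ValueError(f"duplicate register identity at address {address}")
        seen.add(ident)
        core = assemble_register_sequence(perm, domains, spacer)
        if bc is not None:
            core = bc.fwd_seq + core + revcomp(bc.rev_seq)
        registers.append(
            RegisterSpec(address=address, permutation=tuple(perm), sequence=core,
                         scheme=scheme, barcode=bc)
        )
    return TapeBlock(registers=registers, scheme=scheme, domains=domains,
                     spacer=spacer, shuffle_key=shuffle_key, block_id=block_id)


# ---------------------------------------------------------------------------
# domain-calling: observed domain order -> register address
# ---------------------------------------------------------------------------

def permutation_to_address(
    observed_order: list[tuple[int, int]],
    block: TapeBlock,
    min_agree: int = 9,
) -> int:
    """Map an observed (slot, domain_id) order to the best-matching address.

    ``observed_order`` may be incomplete.  The address whose permutation
    agrees with the most observed slots wins; ties or fewer than
    ``min_agree`` agreements return :data:`UNADDRESSED`.
    """
    n_domains = len(block.domains)
    for slot, did in observed_order:
        if not 0 <= did < n_domains:
            raise ValueError(f"observed domain_id {did} not in 0..{n_domains - 1}")
        if not 0 <= slot < n_domains:
            raise ValueError(f"slot {slot} not in 0..{n_domains - 1}")
    if not observed_order:
        return UNADDRESSED
    perms = block.permutation_matrix()
    slots = np.array([s for s, _ in observed_order])
    dids = np.array([d for _, d in observed_order])
    agree = (perms[:, slots] == dids[None, :]).sum(axis=1)
    best = int(agree.max())
    if best < min_agree:
        return UNADDRESSED
    winners = np.flatnonzero(agree == best)
    if len(winners) != 1:
        return UNADDRESSED
    return int(winners[0])


# ---------------------------------------------------------------------------
# reference FASTA / domain TSV I/O
# ---------------------------------------------------------------------------

def write_domains_tsv(domains: list[DomainSpec], path) -> None:
    """Domain definition table: domain_id, state_seq, index_seq."""
    with open(path, "w") as fh:
        fh.write("domain_id\tstate_seq\tindex_seq\n")
        for d in domains:
            fh.write(f"{d.domain_id}\t{d.state_seq}\t{d.index_seq}\n")


def read_domains_tsv(path) -> list[DomainSpec]:
    domains = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["domain_id", "state_seq", "index_seq"]:
            raise ValueError(f"{path}: unexpected domain table header {header}")
        for line in fh:
            did, state, index = line.strip().split("\t")
            domains.append(DomainSpec.from_sequences(int(did), state, index))
    return sorted(domains, key=lambda d: d.domain_id)

def write_reference_fasta(block: TapeBlock, path) -> None:
    """One record per register, header ``reg_<address>|scheme=<s>``."""
    if block.n_registers == 0:
        logger.warning("writing empty reference FASTA for block %s", block.block_id)
    records = [
        SeqRecord(Seq(r.sequence), id=f"reg_{r.address}|scheme={block.scheme}",
                  description="")
        for r in block.registers
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path, domains: list[DomainSpec] | None = None) -> TapeBlock:
    """Rebuild a TapeBlock from its reference FASTA.

    Permutations are recovered by locating each domain's index sequence in
    the register sequence, so the domain set (default if omitted) must be
    the one the block was built with.
    """
    if domains is None:
        domains = default_domains()
    registers = []
    scheme = "high_entropy"
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, tag = rec.id.partition("|")
        address = int(name.removeprefix("reg_"))
        scheme = tag.removeprefix("scheme=") or scheme
        seq = str(rec.seq)
        located = sorted(
            (seq.find(d.index_seq), d.domain_id)
            for d in domains
            if seq.find(d.index_seq) >= 0
        )
        perm = tuple(did for _, did in located)
        registers.append(
            RegisterSpec(address=address, permutation=perm, sequence=seq, scheme=scheme)
        )
    registers.sort(key=lambda r: r.address)
    return TapeBlock(registers=registers, scheme=scheme, domains=domains)
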