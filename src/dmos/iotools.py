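"""Run configuration, bitmap payload codec and demo fixture generation."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import decode as _decode
from . import ldpc as _ldpc
from . import simulate as _sim
from . import tape as _tape


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TapeConfig:
    n_registers: int = 48
    scheme: str = "high_entropy"
    shuffle_key: int = 0
    spacer: str = ""
    min_agree: int = 9


@dataclass
class CodeConfig:
    family: str = "protograph_AR4JA"
    rate: str = "3/4"
    expansion: int = 96


@dataclass
class SimulateConfig:
    n_reads: int = 4800
    seed: int = 0
    p_site_on: float = 0.8
    p_site_off: float = 0.005
    pam_proximal_factor: float = 0.1
    p_sub: float = 0.03
    p_ins: float = 0.02
    p_del: float = 0.03
    p_truncate: float = 0.1
    p_reverse: float = 0.5
    q_mean: float = 12.0
    q_sd: float = 3.0
    n_training_reads: int = 400


@dataclass
class DecodeConfig:
    min_mean_q: float = 9.0
    min_reads_per_bit: int = 5
    delta: float = 0.1
    llr_cap: float = 4.0
    snapshot_interval: int = 100
    n_boot: int = 250
    max_iters: int = 100


@dataclass
class RunConfig:
    tape: TapeConfig = field(default_factory=TapeConfig)
    code: CodeConfig = field(default_factory=CodeConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    decode: DecodeConfig = field(default_factory=DecodeConfig)

    def validate(self) -> "RunConfig":
        s = self.simulate
        for name in ("p_site_on", "p_site_off", "pam_proximal_factor", "p_sub",
                     "p_ins", "p_del", "p_truncate", "p_reverse"):
            v = getattr(s, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"simulate.{name}={v} outside [0,1]")
        if self.tape.scheme not in _tape.SCHEMES:
            raise ValueError(f"tape.scheme={self.tape.scheme!r} unknown")
        if not 0.0 <= self.decode.delta <= 0.5:
            raise ValueError("decode.delta must be in [0, 0.5]")
        return self

    def mutation_model(self) -> _sim.MutationModel:
        return _sim.MutationModel(
            p_site_on=self.simulate.p_site_on,
            p_site_off=self.simulate.p_site_off,
            pam_proximal_factor=self.simulate.pam_proximal_factor,
        )

    def error_model(self) -> _sim.SequencingErrorModel:
        s = self.simulate
        return _sim.SequencingErrorModel(
            p_sub=s.p_sub, p_ins=s.p_ins, p_del=s.p_del,
            p_truncate=s.p_truncate, p_reverse=s.p_reverse,
            q_mean=s.q_mean, q_sd=s.q_sd,
        )


def _update_section(obj, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown config key {section}.{key}")
        setattr(obj, key, type(getattr(obj, key))(value)
                if not isinstance(value, type(getattr(obj, key))) else value)


def load_config(path=None, overrides: list[str] | None = None) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected.

    ``overrides`` are dotted ``section.key=value`` strings (CLI --set).
    """
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sections = {f.name for f in dataclasses.fields(cfg)}
        for section, values in data.items():
            if section not in sections:
                raise ValueError(f"unknown config section {section!r}")
            _update_section(getattr(cfg, section), values or {}, section)
    for item in overrides or []:
        key, _, value = item.partition("=")
        section, _, name = key.partition(".")
        if not name:
            raise ValueError(f"override {item!r} must be section.key=value")
        _update_section(getattr(cfg, section), {name: yaml.safe_load(value)}, section)
    return cfg.validate()


def save_metadata(path, **fields) -> None:
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=1, default=str)


def load_metadata(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# bitmap payloads (plain PBM, P1)
# ---------------------------------------------------------------------------

@dataclass
class BitmapPayload:
    width: int
    height: int
    bits: np.ndarray  # row-major, 1 = black pixel = mutated bit

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.width * self.height != self.bits.size:
            raise ValueError("width*height != number of bits")


def read_pbm(path) -> BitmapPayload:
    """Read a plain (P1) PBM image into a bitmap payload."""
    tokens = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise ValueError(f"{path}: not a plain PBM (P1) file")
    if len(tokens) < 3:
        raise ValueError(f"{path}: missing PBM dimensions")
    width, height = int(tokens[1]), int(tokens[2])
    bits = np.array([int(t) for t in tokens[3: 3 + width * height]], dtype=np.uint8)
    if bits.size != width * height:
        raise ValueError(f"{path}: expected {width * height} pixels, got {bits.size}")
    if not np.isin(bits, (0, 1)).all():
        raise ValueError(f"{path}: PBM pixels must be 0 or 1")
    return BitmapPayload(width=width, height=height, bits=bits)


def write_pbm(bitmap: BitmapPayload, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"P1\n{bitmap.width} {bitmap.height}\n")
        rows = bitmap.bits.reshape(bitmap.height, bitmap.width)
        for row in rows:
            fh.write(" ".join(str(int(b)) for b in row) + "\n")


# ---------------------------------------------------------------------------
# one-call end-to-end pipeline (shared by the CLI demo and analyses)
# ---------------------------------------------------------------------------

def run_pipeline(
    payload: bytes,
    seed: int = 0,
    n_reads: int = 4800,
    config: RunConfig | None = None,
) -> dict:
    """Encode -> write -> sequence -> decode one payload; report accuracy.

    One complete seeded round trip at the standard study conditions: the
    payload is LDPC-encoded, laid on a 48-register high-entropy block,
    written and read through the default simulated channel, and decoded
    with a signature profile fitted from seeded training conditions.

    Returns a dict with the recovered payload, the fraction of payload
    bits recovered, snapshots and the final bit-call table.
    """
    cfg = config or RunConfig()
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0x7ABE])
    sim_seed, train_seed = [int(s) % 2**31 for s in ss.generate_state(2)]
    block = _tape.build_block(
        n_registers=cfg.tape.n_registers, scheme=cfg.tape.scheme,
        shuffle_key=cfg.tape.shuffle_key, spacer=cfg.tape.spacer)
    code = _ldpc.build_code(cfg.code.family, cfg.code.rate, cfg.code.expansion)
    messages = _ldpc.pack_payload(payload, code)
    if len(messages) != 1:
        raise ValueError("run_pipeline handles single-codeword payloads")
    msg = messages[0]
    cw = _ldpc.ldpc_encode(msg, code)
    plan = _ldpc.codeword_to_plan(cw, block)
    mut_model = cfg.mutation_model()
    err_model = cfg.error_model()
    reads = _sim.sample_reads(block, plan, n_reads, mut_model, err_model,
                              rng=sim_seed)
    training, conditions = _sim.make_training_reads(
        block, cfg.simulate.n_training_reads, mut_model, err_model, rng=train_seed)
    profile = _sim.fit_signature_profile(training, conditions, block,
                                         rng=train_seed)
    truth_bits = _ldpc.plan_to_bits(plan, block, code.n)
    message, snapshots, table = _decode.decode_stream(
        reads, block, code, profile, truth_bits=truth_bits,
        truth_message=msg.bits,
        snapshot_interval=cfg.decode.snapshot_interval,
        min_mean_q=cfg.decode.min_mean_q, min_agree=cfg.tape.min_agree,
        min_reads_per_bit=cfg.decode.min_reads_per_bit,
        delta=cfg.decode.delta, llr_cap=cfg.decode.llr_cap,
        max_iters=cfg.decode.max_iters)
    n_payload_bits = 8 * len(payload)
    bit_ok = np.mean(message.bits[:n_payload_bits] == msg.bits[:n_payload_bits])
    recovered = _ldpc.unpack_messages(
        [_ldpc.Message(message.bits, len(payload))])
    return {
        "payload_out": recovered,
        "payload_bit_accuracy": float(bit_ok),
        "payload_exact": recovered == payload,
        "snapshots": snapshots,
        "table": table,
        "block": block,
        "code": code,
        "plan": plan,
    }


# ---------------------------------------------------------------------------
# demo fixtures
# ---------------------------------------------------------------------------

def make_demo_fixtures(outdir, seed: int = 0) -> dict:
    """Small self-contained inputs for demos and CI.

    Emits a 4-register mini tape block (FASTA), a 16-byte text payload, a
    toy short LDPC code description, a 128-bit demo bitmap, and 2,000
    simulated reads with ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    block = _tape.build_block(n_registers=4, scheme="high_entropy", shuffle_key=seed,
                              block_id=f"demo{seed}")
    _tape.write_reference_fasta(block, outdir / "mini_block.fasta")
    payload = b"DMOS demo tape!!"
    (outdir / "payload.bin").write_bytes(payload)
    toy = _ldpc.build_code("regular", "1/2", expansion=2)
    save_metadata(outdir / "toy_code.json", name=toy.name, family=toy.family,
                  rate="1/2", expansion=toy.expansion, k=toy.k, n=toy.n)
    bmp = BitmapPayload(width=16, height=8,
                        bits=rng.integers(0, 2, size=128).astype(np.uint8))
    write_pbm(bmp, outdir / "demo_bitmap.pbm")
    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8))[: 4 * _tape.N_DOMAINS]
    plan = _ldpc.raw_bits_to_plan(bits, block)
    _ldpc.plan_to_csv(plan, outdir / "demo_plan.csv")
    reads = _sim.sample_reads(block, plan, 2000, rng=rng)
    _sim.write_fastq(reads, outdir / "demo_reads.fastq")
    _sim.write_truth(reads, outdir / "demo_truth.tsv")
    save_metadata(outdir / "metadata.json", block_id=block.block_id,
                  scheme=block.scheme, n_registers=4, seed=seed,
                  payload_len=len(payload))
    return {"block": block, "plan": plan, "reads": reads, "payload": payload}
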