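"""Synthetic nanopore signal with exact ground-truth alignments.

Reads are simulated from a known k-mer model: each base dwells an integer
truncated-normal number of samples (default mean 30, bounds [20, 40] — the
regime of 130 bases/s sampled at 4 kHz) and emits Gaussian current around
the level of the k-mer window anchored at that base, with the model's
per-k-mer spread.  The emitted ss string records the segmentation exactly,
so the sampling, building, significance and evaluation stages can all be
exercised with no external data.

Sequences are either uniform random over ACGT or cut from a de Bruijn
super-sequence of order k, in which every k-mer occurs once per pass —
the cheapest way to drive every k-mer to a target observation depth.

Levels in the truth model are in normalized units; simulated traces are
placed on a pA-like scale (``pa = level * scale_sd + scale_mean``) and then
quantized to ADC integers, so the full raw -> pA -> Med-MAD path is
exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alignments import PafRecord
from .model_io import ALPHABET, KmerModel
from .signals import ReadRecord
from .ss import OpKind, SsAlignment, SsOp

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "corrupt_alignment",
    "de_bruijn_sequence",
    "random_truth_model",
    "weighted_truth_model",
    "expected_samples_per_base",
    "reads_for_target_depth",
]


def expected_samples_per_base(
    translocation_speed: float = 130.0, sampling_rate: float = 4000.0
) -> int:
    """Samples per base at a given translocation speed and sampling rate.

    130 bases/s at 4000 Hz gives floor(4000/130) = 30 samples/base.
    """
    if translocation_speed <= 0 or sampling_rate <= 0:
        raise ValueError("speed and rate must be positive")
    return int(sampling_rate // translocation_speed)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    truth_model: KmerModel
    n_reads: int = 20
    read_length: int = 500  # bases
    dwell_mean: float = 30.0
    dwell_sd: float = 3.0
    dwell_min: int = 20
    dwell_max: int = 40
    rna_mode: bool = False
    de_bruijn: bool = False  # cut reads from a k-mer-covering super-sequence
    scale_mean: float = 100.0  # pA placement of normalized level 0
    scale_sd: float = 20.0  # pA per normalized unit
    digitisation: float = 8192.0
    range_pA: float = 1500.0
    adc_offset: float = 10.0
    sampling_rate: float = 4000.0
    seed: int = 7


@dataclass
class SimulatedDataset:
    records: list[ReadRecord]
    alignments: dict[str, SsAlignment]
    truth_model: KmerModel
    config: SimConfig

    def paf_records(self) -> list[PafRecord]:
        out = []
        for rec in self.records:
            aln = self.alignments[rec.read_id]
            out.append(
                PafRecord(
                    read_id=rec.read_id,
                    signal_len=rec.raw.size,
                    target_name=rec.read_id,
                    target_len=len(rec.sequence),
                    alignment=aln,
                )
            )
        return out

    def fasta_text(self) -> str:
        return "".join(f">{r.read_id}\n{r.sequence}\n" for r in self.records)


def de_bruijn_sequence(
    k: int,
    alphabet: tuple[str, ...] = ALPHABET,
    rng: np.random.Generator | None = None,
) -> str:
    """Linearized de Bruijn sequence of order k: every k-mer occurs once.

    Returns a string of length ``|A|**k + k - 1`` whose sliding windows
    enumerate each k-mer exactly once.  With ``rng`` the underlying cycle
    is a random Eulerian circuit of the de Bruijn graph, so local base
    composition is balanced like a random sequence — contiguous chunks of
    the deterministic (Lyndon-word) ordering are heavily composition-biased,
    which per-read normalization cannot absorb.  Without ``rng`` the
    deterministic Lyndon-word concatenation is used.
    """
    n = len(alphabet)
    if rng is None:
        sequence: list[int] = []
        a = [0] * n * k

        def db(t: int, p: int) -> None:
            if t > k:
                if k % p == 0:
                    sequence.extend(a[1 : p + 1])
            else:
                a[t] = a[t - p]
                db(t + 1, p)
                for j in range(a[t - p] + 1, n):
                    a[t] = j
                    db(t + 1, t)

        db(1, 1)
        cyc = "".join(alphabet[i] for i in sequence)
        return cyc + cyc[: k - 1]

    if k == 1:
        order = list(rng.permutation(n))
        return "".join(alphabet[i] for i in order)
    # Hierholzer over nodes = (k-1)-mers, edges = k-mers, random edge order.
    nodes = [""]
    for _ in range(k - 1):
        nodes = [v + b for v in nodes for b in alphabet]
    adj = {
        v: [alphabet[i] for i in rng.permutation(n)] for v in nodes
    }
    next_edge = {v: 0 for v in nodes}
    start = nodes[0]
    stack = [start]
    circuit: list[str] = []
    while stack:
        v = stack[-1]
        if next_edge[v] < n:
            b = adj[v][next_edge[v]]
            next_edge[v] += 1
            stack.append(v[1:] + b)
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    # circuit visits 4**k + 1 nodes; drop the duplicated start, keep the
    # cyclic sequence of edge labels (last char of each node after the first)
    return circuit[0] + "".join(v[-1] for v in circuit[1:])


def random_truth_model(
    k: int, seed: int = 0, level_sd: float = 1.0, event_sd: tuple[float, float] = (0.1, 0.3)
) -> KmerModel:
    """Complete model with Normal(0, level_sd) levels and uniform spreads."""
    rng = np.random.default_rng(seed)
    kmers = _all_kmers(k)
    mus = rng.normal(0.0, level_sd, size=len(kmers))
    sds = rng.uniform(*event_sd, size=len(kmers))
    return KmerModel(
        k=k,
        levels={km: (float(m), float(s)) for km, m, s in zip(kmers, mus, sds)},
        space="normalized",
    )


def weighted_truth_model(
    k: int,
    weights: list[float],
    noise_sd: float = 0.0,
    event_sd: float = 0.2,
    seed: int = 0,
) -> KmerModel:
    """Model whose level is a weighted sum of per-position base codes.

    ``level(kmer) = sum_i weights[i] * code(kmer[i]) + Normal(0, noise_sd)``
    with codes A,C,G,T -> -1.5,-0.5,0.5,1.5.  Positions with zero weight
    contribute nothing, so they should never be reported significant.
    """
    if len(weights) != k:
        raise ValueError("need one weight per position")
    rng = np.random.default_rng(seed)
    code = {b: i - 1.5 for i, b in enumerate(ALPHABET)}
    levels = {}
    for kmer in _all_kmers(k):
        mu = sum(w * code[b] for w, b in zip(weights, kmer))
        if noise_sd > 0:
            mu += rng.normal(0.0, noise_sd)
        levels[kmer] = (float(mu), event_sd)
    return KmerModel(k=k, levels=levels, space="normalized")


def _all_kmers(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [km + b for km in kmers for b in ALPHABET]
    return kmers


def reads_for_target_depth(
    target_depth: int, k: int, read_length: int, retention: float = 0.9
) -> int:
    """Reads needed (de Bruijn mode) so every k-mer stores >= target_depth.

    One pass over the de Bruijn super-sequence observes each k-mer once;
    ``retention`` discounts events lost to the dwell filter.
    """
    if read_length < 2 * k:
        raise ValueError("read_length too short to tile k-mers")
    passes = math.ceil(target_depth / retention)
    super_len = 4**k + k - 1
    reads_per_pass = math.ceil(super_len / (read_length - (k - 1)))
    return passes * reads_per_pass


def _integer_truncnorm(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    d = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.clip(d, lo, hi)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Simulate reads, raw signals and exact ground-truth ss alignments.

    In de Bruijn mode the super-sequence is cut into reads of
    ``read_length`` with k-1 bases of overlap, cycling until ``n_reads``
    are produced; every full cycle of reads covers each k-mer once.  If the
    read budget cannot cover the super-sequence even once, an error reports
    the number of reads required.
    """
    model = cfg.truth_model
    k = model.k
    if model.completeness() < 1.0:
        raise ValueError("truth model must be complete")
    rng = np.random.default_rng(cfg.seed)

    if cfg.de_bruijn:
        super_seq = de_bruijn_sequence(k, rng=rng)
        step = cfg.read_length - (k - 1)
        starts = list(range(0, len(super_seq) - (k - 1), step))
        reads_per_pass = len(starts)
        if cfg.n_reads < reads_per_pass:
            raise ValueError(
                f"read budget {cfg.n_reads} cannot cover all {4**k} k-mers "
                f"once; need at least {reads_per_pass} reads of length "
                f"{cfg.read_length} (use reads_for_target_depth)"
            )
        seqs = [
            super_seq[s : s + cfg.read_length]
            for s in (starts[i % reads_per_pass] for i in range(cfg.n_reads))
        ]
    else:
        seqs = [
            "".join(rng.choice(list(ALPHABET), size=cfg.read_length))
            for _ in range(cfg.n_reads)
        ]

    levels = model.levels
    records: list[ReadRecord] = []
    alignments: dict[str, SsAlignment] = {}
    for idx, seq in enumerate(seqs):
        if len(seq) < k:
            raise ValueError(f"read length {len(seq)} shorter than k={k}")
        traversal = seq[::-1] if cfg.rna_mode else seq
        n = len(traversal)
        dwell = _integer_truncnorm(
            rng, n, cfg.dwell_mean, cfg.dwell_sd, cfg.dwell_min, cfg.dwell_max
        )
        mus = np.empty(n)
        sds = np.empty(n)
        last = None
        for i in range(n):
            window = traversal[i : i + k]
            if len(window) == k:
                kmer = window[::-1] if cfg.rna_mode else window
                last = levels[kmer]
            mu, sd = last  # tail bases reuse the final full window
            mus[i] = mu
            sds[i] = 0.0 if sd is None else sd
        per_sample_mu = np.repeat(mus, dwell)
        per_sample_sd = np.repeat(sds, dwell)
        pa = (
            per_sample_mu * cfg.scale_sd
            + cfg.scale_mean
            + rng.normal(0.0, 1.0, per_sample_mu.size) * per_sample_sd * cfg.scale_sd
        )
        raw = np.rint(
            pa * cfg.digitisation / cfg.range_pA - cfg.adc_offset
        ).astype(np.int32)
        read_id = f"sim_{idx:05d}"
        records.append(
            ReadRecord(
                read_id=read_id,
                raw=raw,
                digitisation=cfg.digitisation,
                range_pA=cfg.range_pA,
                offset=cfg.adc_offset,
                sampling_rate=cfg.sampling_rate,
                sequence=seq,
            )
        )
        alignments[read_id] = SsAlignment(
            ops=[SsOp(OpKind.MATCH, int(d)) for d in dwell],
            signal_start=0,
            seq_start=0,
        )
    return SimulatedDataset(
        records=records, alignments=alignments, truth_model=model, config=cfg
    )


def corrupt_alignment(
    aln: SsAlignment,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    jitter: int = 0,
    seed: int = 0,
) -> SsAlignment:
    """Degrade an all-match alignment with indels and boundary jitter.

    Per match run: with ``del_rate`` the base is deleted (its samples
    become an insertion); with ``ins_rate`` an insertion of ~jitter+1
    samples is carved out of the run; boundaries shift by +/- jitter
    samples while conserving total signal.  Seeded and deterministic.
    """
    rng = np.random.default_rng(seed)
    durations = [op.length for op in aln.ops if op.kind is OpKind.MATCH]
    if len(durations) != len(aln.ops):
        raise ValueError("corrupt_alignment expects an all-match alignment")
    if jitter > 0:
        for i in range(len(durations) - 1):
            j = int(rng.integers(-jitter, jitter + 1))
            j = max(-durations[i] + 1, min(j, durations[i + 1] - 1))
            durations[i] += j
            durations[i + 1] -= j
    ops: list[SsOp] = []
    for d in durations:
        u = rng.random()
        if u < del_rate:
            if ops and ops[-1].kind is OpKind.DELETION:
                prev = ops.pop()
                ops.append(SsOp(OpKind.DELETION, prev.length + 1))
            else:
                ops.append(SsOp(OpKind.DELETION, 1))
            ops.append(SsOp(OpKind.INSERTION, d))
        elif u < del_rate + ins_rate and d > jitter + 2:
            cut = jitter + 1
            ops.append(SsOp(OpKind.INSERTION, cut))
            ops.append(SsOp(OpKind.MATCH, d - cut))
        else:
            ops.append(SsOp(OpKind.MATCH, d))
    return replace(aln, ops=ops)
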