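"""Synthetic selection-sequencing reads, kinetic time courses and melting
curves with known ground truth.

The generator mirrors the statistical structure the analysis assumes rather
than the chemistry producing it:

* every variant v of the randomized region carries a true acylation
  probability p_v (chance its terminus is protected and survives selection)
  and a procedural bias b_v > 0 (relative ligation/RT/PCR propensity, drawn
  log-normal with median 1);
* a selection sample draws reads multinomially with probabilities
  proportional to p_v * b_v, the blank proportional to b_v alone — so the
  selection/blank frequency ratio converges to p_v up to a normalization;
* reads are the fixed flanks around the variant with i.i.d. per-base
  substitution errors, written to FASTQ in DNA letters (U as T) with a
  constant 'I' quality line.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .duplex_thermo import DuplexThermo, MeltingCurve, melting_signal
from .transfer_kinetics import TimeCourse, TransferKinetics, yield_model
from .variant_counting import LibraryDesign, ReadSet, enumerate_variants

_RNA_TO_DNA = str.maketrans("U", "T")
_DNA_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated screen over the full variant space."""

    variants: list[str]
    p: np.ndarray
    b: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.variants)
        if len(self.p) != n or len(self.b) != n:
            raise ValueError("p and b must match the number of variants")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("acylation probabilities must lie in [0, 1]")
        if np.any(self.b <= 0):
            raise ValueError("procedural biases must be positive")

    @property
    def k(self) -> int:
        return len(self.variants[0])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"variant": self.variants, "p": self.p, "b": self.b}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, seed: int = 0) -> "SimulationTruth":
        df = pd.read_csv(path, sep="\t")
        return cls(variants=list(df["variant"]), p=df["p"].to_numpy(),
                   b=df["b"].to_numpy(), seed=seed)


def make_truth(k: int, bias_sd: float = 0.5,
               p_spec: float | Mapping[str, float] | tuple = ("uniform", 0.05, 0.95),
               seed: int = 0) -> SimulationTruth:
    """Draw a ground truth over all 4**k variants.

    ``bias_sd`` is the log-sd of the log-normal procedural bias (median 1;
    0 gives b = 1 everywhere).  ``p_spec`` sets acylation probabilities:
    a scalar applies to every variant, a mapping assigns them explicitly
    (missing variants get 0), and a tuple names a distribution —
    ("uniform", lo, hi) or ("beta", a, b).  Deterministic given ``seed``.
    """
    if bias_sd < 0:
        raise ValueError("bias_sd must be >= 0")
    variants = enumerate_variants(k)
    n = len(variants)
    rng = np.random.default_rng(seed)
    b = np.exp(rng.normal(0.0, bias_sd, size=n)) if bias_sd > 0 else np.ones(n)

    if isinstance(p_spec, Mapping):
        unknown = set(p_spec) - set(variants)
        if unknown:
            raise ValueError(f"p_spec names off-design variants: {sorted(unknown)[:5]}")
        p = np.array([float(p_spec.get(v, 0.0)) for v in variants])
    elif isinstance(p_spec, tuple):
        kind, *args = p_spec
        if kind == "uniform":
            lo, hi = args
            p = rng.uniform(lo, hi, size=n)
        elif kind == "beta":
            a, bb = args
            p = rng.beta(a, bb, size=n)
        else:
            raise ValueError(f"unknown p distribution {kind!r}")
    else:
        p = np.full(n, float(p_spec))
    return SimulationTruth(variants=variants, p=p, b=b, seed=seed)


def expected_frequencies(truth: SimulationTruth) -> tuple[np.ndarray, np.ndarray]:
    """Exact multinomial cell probabilities for (selection, blank) reads."""
    w_sel = truth.p * truth.b
    if w_sel.sum() == 0:
        raise ValueError("all selection weights are zero")
    return w_sel / w_sel.sum(), truth.b / truth.b.sum()


def _mutate(read_bytes: np.ndarray, error_rate: float,
            rng: np.random.Generator) -> np.ndarray:
    """I.i.d. substitutions: each error site is replaced by one of the
    three other bases, uniformly."""
    if error_rate == 0:
        return read_bytes
    mask = rng.random(read_bytes.shape) < error_rate
    if not mask.any():
        return read_bytes
    shift = rng.integers(1, 4, size=int(mask.sum()))
    lut = np.zeros(256, dtype=np.int64)
    for i, base in enumerate(_DNA_BASES):
        lut[base] = i
    idx = (lut[read_bytes[mask]] + shift) % 4
    read_bytes = read_bytes.copy()
    read_bytes[mask] = _DNA_BASES[idx]
    return read_bytes


def simulate_selection_reads(truth: SimulationTruth, design: LibraryDesign,
                             depth: int = 100_000, error_rate: float = 0.001,
                             seed: int = 0) -> tuple[ReadSet, ReadSet]:
    """Draw paired (selection, blank) read sets of ``depth`` reads each.

    Selection counts are multinomial with cell probabilities proportional to
    p_v*b_v, blank counts proportional to b_v; each read is
    flank + variant + flank in DNA letters with i.i.d. substitutions at
    ``error_rate``.  Read order is shuffled so downstream code cannot rely
    on grouping.  Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if design.k != truth.k:
        raise ValueError("design k does not match truth variants")
    rng = np.random.default_rng(seed)
    f_sel, f_blank = expected_frequencies(truth)
    counts_sel = rng.multinomial(depth, f_sel)
    counts_blank = rng.multinomial(depth, f_blank)

    def emit(counts: np.ndarray, label: str) -> ReadSet:
        templates = []
        for v, c in zip(truth.variants, counts):
            if c:
                dna = (design.upstream_flank + v + design.downstream_flank
                       ).translate(_RNA_TO_DNA)
                templates.append((dna, int(c)))
        n_total = int(counts.sum())
        length = design.read_length
        block = np.empty((n_total, length), dtype=np.uint8)
        row = 0
        for dna, c in templates:
            block[row:row + c] = np.frombuffer(dna.encode(), dtype=np.uint8)
            row += c
        block = _mutate(block, error_rate, rng)
        order = rng.permutation(n_total)
        reads = [block[i].tobytes().decode() for i in order]
        return ReadSet(condition_label=label, reads=reads, design=design)

    sel = emit(counts_sel, "selection")
    blank = emit(counts_blank, "blank")
    return sel, blank


def write_fastq(readset: ReadSet, path: str | Path,
                id_prefix: str = "read") -> None:
    """Write a ReadSet as plain 4-line FASTQ with constant 'I' qualities."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, seq in enumerate(readset.reads):
            fh.write(f"@{id_prefix}_{readset.condition_label}_{i}\n{seq}\n+\n"
                     f"{'I' * len(seq)}\n")


def simulate_time_course(kin: TransferKinetics, times: Sequence[float],
                         noise_sd: float = 0.0, seed: int = 0,
                         label: str = "simulated") -> TimeCourse:
    """Closed-form yield curve plus Gaussian noise truncated to [0, 1]."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    y = yield_model(times, kin)
    y = np.atleast_1d(y).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sd, size=y.shape), 0.0, 1.0)
    return TimeCourse(times=times, yields=y, label=label)


def simulate_melting_curve(thermo: DuplexThermo, temps: Sequence[float],
                           baselines: Sequence[float] = (0.0, 1.0, 0.0, 0.0),
                           noise_sd: float = 0.0, seed: int = 0,
                           label: str = "simulated") -> MeltingCurve:
    """Two-state melting signal with sloping baselines and Gaussian noise.

    ``baselines`` are (m_ss, c_ss, m_ds, c_ds): slope and intercept of the
    single-strand and double-strand baselines.
    """
    temps = np.asarray(temps, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    signal = melting_signal(thermo, temps, tuple(baselines))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return MeltingCurve(temps=temps, signals=signal, label=label)
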