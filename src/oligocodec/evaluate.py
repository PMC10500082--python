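"""Cost metrics and the decoding-success-versus-sampling-number harness.

Writing cost is synthesized bases per information bit, reading cost is
sequenced bases per information bit, and their trade-off is the central
economy of DNA-based data storage.  ``run_sweep`` measures the empirical
success-rate curve of the codec over a grid of random sampling numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .channel import ChannelParams, sample_reads
from .config import EncodingConfig
from .decoder import decode_reads
from .encoder import OligoRecord
from .ldpc import LDPCCode


@dataclass
class CostReport:
    """Writing/reading cost bookkeeping; density is the inverse of writing
    cost.  Reading cost uses the convention sampled reads x nominal read
    length / information bits."""

    writing_cost: float
    information_density: float
    reading_cost: float | None
    coverage: float | None

    def as_dict(self) -> dict:
        return {
            "writing_cost_bases_per_bit": round(self.writing_cost, 2),
            "information_density_bits_per_nt": round(
                self.information_density, 2
            ),
            "reading_cost_bases_per_bit": (
                None if self.reading_cost is None
                else round(self.reading_cost, 2)
            ),
            "coverage_reads_per_oligo": (
                None if self.coverage is None else round(self.coverage, 2)
            ),
        }


def writing_cost(total_payload_bases: int, info_bits: int) -> float:
    """Synthesized bases divided by information bits."""
    if info_bits <= 0:
        raise ValueError("info_bits must be positive")
    return total_payload_bases / info_bits


def information_density(total_payload_bases: int, info_bits: int) -> float:
    return info_bits / total_payload_bases


def reading_cost(
    sampling_number: int, read_len: int, info_bits: int
) -> float:
    """Sequenced bases (sampled reads x nominal read length) per info bit."""
    if info_bits <= 0:
        raise ValueError("info_bits must be positive")
    return sampling_number * read_len / info_bits


def coverage(sampling_number: int, total_oligos: int) -> float:
    """Sampled reads per designed oligo sequence."""
    if total_oligos <= 0:
        raise ValueError("total_oligos must be positive")
    return sampling_number / total_oligos


def cost_report(
    config: EncodingConfig, sampling_number: int | None = None
) -> CostReport:
    bases = config.total_oligos * config.oligo_nt
    bits = config.payload_oligos * config.payload_bits
    return CostReport(
        writing_cost=writing_cost(bases, bits),
        information_density=information_density(bases, bits),
        reading_cost=(
            None
            if sampling_number is None
            else reading_cost(sampling_number, config.oligo_nt, bits)
        ),
        coverage=(
            None
            if sampling_number is None
            else coverage(sampling_number, config.total_oligos)
        ),
    )


@dataclass
class SweepResult:
    sampling_numbers: list[int]
    trials: int
    successes: list[int] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    @property
    def success_rates(self) -> list[float]:
        return [s / self.trials for s in self.successes]

    def to_tsv(self, path: str | Path, config: EncodingConfig) -> None:
        bits = config.payload_oligos * config.payload_bits
        with Path(path).open("w") as fh:
            fh.write(
                "# reading cost = sampling_number x nominal read length "
                f"({config.oligo_nt} nt) / information bits ({bits})\n"
            )
            fh.write(
                "sampling_number\tcoverage\treading_cost\t"
                "successes\ttrials\tsuccess_rate\n"
            )
            for n, s in zip(self.sampling_numbers, self.successes):
                fh.write(
                    f"{n}\t{coverage(n, config.total_oligos):.3f}\t"
                    f"{reading_cost(n, config.oligo_nt, bits):.3f}\t"
                    f"{s}\t{self.trials}\t{s / self.trials:.3f}\n"
                )


def run_sweep(
    pool: list[OligoRecord],
    code: LDPCCode,
    config: EncodingConfig,
    original: bytes,
    sampling_numbers: list[int],
    trials: int,
    params: ChannelParams,
    seed: int = 0,
    use_vl: bool = True,
    use_qscore: bool = True,
) -> SweepResult:
    """Success-rate curve: for each sampling number run sample->decode
    ``trials`` times; success = byte-identical recovery with a passing CRC.

    Trial seeds derive deterministically from (seed, level, trial), so the
    sweep is reproducible and decode failures count as unsuccessful trials.
    """
    result = SweepResult(list(sampling_numbers), trials)
    ss = np.random.SeedSequence(seed)
    for level, n_samp in enumerate(sampling_numbers):
        wins = 0
        for t in range(trials):
            trial_seed = int(
                np.random.SeedSequence([seed, level, t]).generate_state(1)[0]
            ) % (2**31)
            result.seeds.append(trial_seed)
            reads = sample_reads(pool, n_samp, params, seed=trial_seed)
            res = decode_reads(
                reads, code, config, use_vl=use_vl, use_qscore=use_qscore,
                channel_params=params,
            )
            if res.success and res.data == original and res.report["crc_ok"]:
                wins += 1
        result.successes.append(wins)
    del ss
    return result


def plot_sweep(result: SweepResult, config: EncodingConfig,
               path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bits = config.payload_oligos * config.payload_bits
    costs = [
        reading_cost(n, config.oligo_nt, bits)
        for n in result.sampling_numbers
    ]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(costs, result.success_rates, "o-")
    ax.set_xlabel("reading cost (bases/bit)")
    ax.set_ylabel("decoding success rate")
    ax.set_ylim(-0.02, 1.02)
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
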