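"""Codec configuration: the constants that define an oligo pool layout.

The production layout stores 548-KB-class payloads in 18 432 oligos of
152 nt: an 8-nt index, 8 nt of RS parity protecting it, and a 136-nt payload
(272 bits).  16 572 oligos carry data, 1 860 carry inter-oligo LDPC parity.
Scaled layouts (fewer, shorter oligos) use the same machinery for fast
experiments; ``scaled_config`` builds one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

PRIMER5 = "GTTCAGAGTTCTACAGTCCGACGATC"  # 26 nt, 5' sequencing primer
PRIMER3 = "TGGAATTCTCGGGTGCCAAGG"  # 21 nt, 3' sequencing primer

INDEX_NT = 8
INDEX_PARITY_NT = 8
FRAME_PREFIX_NT = INDEX_NT + INDEX_PARITY_NT  # 16 nt of index + RS parity


@dataclass
class EncodingConfig:
    """Everything needed to reproduce an encoding bit-for-bit."""

    total_oligos: int = 18432
    payload_oligos: int = 16572
    payload_nt: int = 136
    prbs_seed: int = 0x5EED5EED
    ldpc_seed: int = 20240901
    column_weight: int = 4
    ldpc_code_path: str | None = None
    primer5: str = PRIMER5
    primer3: str = PRIMER3
    with_primers: bool = False

    # decoder-side thresholds (kept here so one file travels with the pool)
    d_th: int = 10
    q_last_gate: int = 30
    q_count_gate: int = 20
    epsilon0: float = 0.02
    delta_epsilon: float = 0.005
    epsilon_end: float = 0.005
    bp_max_iter: int = 50

    @property
    def index_nt(self) -> int:
        return INDEX_NT

    @property
    def index_parity_nt(self) -> int:
        return INDEX_PARITY_NT

    @property
    def oligo_nt(self) -> int:
        return FRAME_PREFIX_NT + self.payload_nt

    @property
    def payload_bits(self) -> int:
        return 2 * self.payload_nt

    @property
    def parity_oligos(self) -> int:
        return self.total_oligos - self.payload_oligos

    @property
    def capacity_bits(self) -> int:
        return self.payload_oligos * self.payload_bits

    def validate(self) -> None:
        if self.payload_oligos >= self.total_oligos:
            raise ValueError("need parity oligos: payload_oligos < total_oligos")
        if self.payload_nt <= 0:
            raise ValueError("payload_nt must be positive")
        if len(self.primer5) != 26 or len(self.primer3) != 21:
            raise ValueError("primers must be the 26-nt / 21-nt pair")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EncodingConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def default_config() -> EncodingConfig:
    return EncodingConfig()


def scaled_config(
    total_oligos: int,
    payload_oligos: int,
    payload_nt: int,
    column_weight: int = 3,
    **kwargs,
) -> EncodingConfig:
    """A reduced-size layout with the same structure as the production one."""
    cfg = EncodingConfig(
        total_oligos=total_oligos,
        payload_oligos=payload_oligos,
        payload_nt=payload_nt,
        column_weight=column_weight,
        **kwargs,
    )
    cfg.validate()
    return cfg
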