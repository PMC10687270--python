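from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from syntenymap.model import (
    BlockSet,
    ChromosomeDef,
    GenomeDef,
    Orientation,
    SyntenyBlock,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_blockset(
    rng: np.random.Generator,
    n: int,
    n_target_chroms: int = 3,
    n_query_chroms: int = 3,
    chrom_span: int = 60_000_000,
    max_len: int = 8_000_000,
    min_len: int = 10_000,
) -> BlockSet:
    """Random blocks with lengths spanning the filter thresholds (log-uniform)."""
    blocks = []
    for _ in range(n):
        length = int(
            np.exp(rng.uniform(np.log(min_len), np.log(max_len)))
        )
        t_start = int(rng.integers(0, chrom_span - length))
        q_len = int(
            np.exp(rng.uniform(np.log(min_len), np.log(max_len)))
        )
        q_start = int(rng.integers(0, chrom_span - q_len))
        blocks.append(
            SyntenyBlock(
                target_chrom=f"t{int(rng.integers(1, n_target_chroms + 1))}",
                target_start=t_start,
                target_end=t_start + length,
                query_chrom=f"q{int(rng.integers(1, n_query_chroms + 1))}",
                query_start=q_start,
                query_end=q_start + q_len,
                orientation=Orientation.SAME
                if rng.integers(2) == 0
                else Orientation.INVERTED,
            )
        )
    return BlockSet("T", "Q", tuple(blocks))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def query_genome() -> GenomeDef:
    return GenomeDef(
        "Q",
        (
            ChromosomeDef("q1", 60_000_000, centromere=20_000_000),
            ChromosomeDef("q2", 60_000_000, centromere=25_000_000),
            ChromosomeDef("q3", 60_000_000),
            ChromosomeDef("qX", 60_000_000, is_autosome=False),
        ),
    )


@pytest.fixture
def small_ancestor() -> GenomeDef:
    return GenomeDef(
        "ANC",
        (
            ChromosomeDef("anc1", 120_000_000),
            ChromosomeDef("anc2", 90_000_000),
            ChromosomeDef("anc3", 70_000_000),
        ),
    )


def make_block(
    t_chrom: str,
    t_start: int,
    t_end: int,
    q_chrom: str = "q1",
    q_start: int | None = None,
    q_end: int | None = None,
    orientation: Orientation = Orientation.SAME,
) -> SyntenyBlock:
    """Shorthand block constructor; query interval mirrors target by default."""
    if q_start is None:
        q_start = t_start
    if q_end is None:
        q_end = q_start + (t_end - t_start)
    return SyntenyBlock(t_chrom, t_start, t_end, q_chrom, q_start, q_end, orientation)
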