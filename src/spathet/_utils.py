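"""Shared helpers: karyotype order, seeding, logging."""

from __future__ import annotations

import logging
import zlib

#: Chromosomes retained for CNV work, in karyotype order. Y and
#: non-canonical contigs (chrM, scaffolds) are dropped on read.
KARYOTYPE: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

_KARYOTYPE_RANK = {c: i for i, c in enumerate(KARYOTYPE)}

logger = logging.getLogger("spathet")


def chrom_rank(chrom: str) -> int:
    """Position of ``chrom`` in karyotype order; raises for unlisted ones."""
    return _KARYOTYPE_RANK[normalize_chrom(chrom)]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix; no validation."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the run seed, salted by stage name.

    Keeps every stage reproducible in isolation while all randomness
    flows from a single configured seed. Result is always < 2**31.
    """
    return (int(base_seed) * 100003 + zlib.crc32(stage.encode("utf-8"))) % (2**31 - 1)
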