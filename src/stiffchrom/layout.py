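"""Chain layout for the block-copolymer nucleus model.

A model chromosome is a linear bead-spring chain whose beads carry one of
three class labels:

* ``A`` / ``B`` — euchromatic / heterochromatic compartment domains of equal
  genomic size, strictly alternating along the chain interior;
* ``TEL`` — telomeric caps at both chain ends.

The default geometry follows the multichain nucleus design used throughout
this package: a 20-Mb chain of 5-kb beads with 1.5-Mb A/B domains and 1-Mb
telomeres, giving six A domains, six B domains and two telomeric blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_A = "A"
CLASS_B = "B"
CLASS_TEL = "TEL"

# integer codes used by the simulation engine
CLASS_CODES = {CLASS_A: 0, CLASS_B: 1, CLASS_TEL: 2}


@dataclass(frozen=True)
class ChainLayout:
    """Per-bead class layout of one model chromosome.

    Attributes
    ----------
    bead_bp:
        Genomic length represented by one bead (bp).
    chain_bp:
        Total genomic length of the chain (bp).
    labels:
        Ordered per-bead class label, each in ``{"A", "B", "TEL"}``.
    block_table:
        Ordered ``(class, start_bead, n_beads)`` tuples covering the chain.
    """

    bead_bp: int
    chain_bp: int
    labels: tuple[str, ...]
    block_table: tuple[tuple[str, int, int], ...] = field(repr=False)

    @property
    def n_beads(self) -> int:
        return len(self.labels)

    @property
    def label_codes(self) -> np.ndarray:
        """Integer codes (A=0, B=1, TEL=2) as an int8 array."""
        return np.array([CLASS_CODES[c] for c in self.labels], dtype=np.int8)

    def n_blocks(self, cls: str) -> int:
        return sum(1 for c, _, _ in self.block_table if c == cls)

    def scaled(self, factor: float) -> "ChainLayout":
        """Return a geometrically scaled layout preserving block proportions.

        ``factor`` multiplies every block's bead count (rounded to >= 1 bead);
        used for desk-scale simulation presets.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        blocks = []
        start = 0
        for cls, _, n in self.block_table:
            m = max(1, int(round(n * factor)))
            blocks.append((cls, start, m))
            start += m
        labels = []
        for cls, _, m in blocks:
            labels.extend([cls] * m)
        return ChainLayout(
            bead_bp=self.bead_bp,
            chain_bp=start * self.bead_bp,
            labels=tuple(labels),
            block_table=tuple(blocks),
        )


def build_chain_layout(
    chain_bp: int = 20_000_000,
    bead_bp: int = 5_000,
    domain_bp: int = 1_500_000,
    telomere_bp: int = 1_000_000,
) -> ChainLayout:
    """Construct a TEL-(A B)xk-TEL chain layout.

    The chain is capped by two telomeric blocks of ``telomere_bp`` each and
    filled in between with strictly alternating A and B domains of
    ``domain_bp`` each; the interior must therefore hold an even number of
    domains (k A-domains and k B-domains).

    Raises
    ------
    ValueError
        If any length is non-positive, ``bead_bp`` does not divide
        ``telomere_bp`` or ``domain_bp``, or the interior length is not an
        even multiple of ``domain_bp``.
    """
    for name, v in [
        ("chain_bp", chain_bp),
        ("bead_bp", bead_bp),
        ("domain_bp", domain_bp),
        ("telomere_bp", telomere_bp),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if telomere_bp % bead_bp != 0:
        raise ValueError(
            f"bead_bp={bead_bp} does not divide telomere_bp={telomere_bp}"
        )
    if domain_bp % bead_bp != 0:
        raise ValueError(f"bead_bp={bead_bp} does not divide domain_bp={domain_bp}")
    interior_bp = chain_bp - 2 * telomere_bp
    if interior_bp <= 0:
        raise ValueError("chain shorter than its two telomeres")
    n_domains, rem = divmod(interior_bp, domain_bp)
    if rem != 0:
        raise ValueError(
            f"interior length {interior_bp} bp is not a multiple of "
            f"domain_bp={domain_bp} (remainder {rem} bp)"
        )
    if n_domains % 2 != 0:
        raise ValueError(
            f"interior holds {n_domains} domains; need an even number for "
            "strict A/B alternation"
        )
    k = n_domains // 2
    if k < 1:
        raise ValueError("need at least one A and one B domain")

    tel_beads = telomere_bp // bead_bp
    dom_beads = domain_bp // bead_bp
    blocks: list[tuple[str, int, int]] = []
    start = 0

    def push(cls: str, n: int) -> None:
        nonlocal start
        blocks.append((cls, start, n))
        start += n

    push(CLASS_TEL, tel_beads)
    for _ in range(k):
        push(CLASS_A, dom_beads)
        push(CLASS_B, dom_beads)
    push(CLASS_TEL, tel_beads)

    labels: list[str] = []
    for cls, _, n in blocks:
        labels.extend([cls] * n)
    assert start * bead_bp == chain_bp
    return ChainLayout(
        bead_bp=bead_bp,
        chain_bp=chain_bp,
        labels=tuple(labels),
        block_table=tuple(blocks),
    )
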