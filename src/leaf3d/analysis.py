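"""Trait-table summaries and the generalized heritability formula."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InsufficientDataError, Leaf3DError
from .grid import TRAIT_NAMES


def summarize_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait mean and [min, max] of a trait table, one trait per row."""
    traits = [t for t in TRAIT_NAMES if t in table.columns]
    if not traits or len(table) == 0:
        raise InsufficientDataError("trait table is empty")
    sub = table[traits]
    return pd.DataFrame({"mean": sub.mean(), "min": sub.min(), "max": sub.max()},
                        index=traits)


def format_summary(summary: pd.DataFrame) -> str:
    lines = [f"{'Trait':<10} {'Mean':>10} {'Range':>22}"]
    for trait, row in summary.iterrows():
        lines.append(f"{trait:<10} {row['mean']:>10.3f} "
                     f"[{row['min']:.3f}, {row['max']:.3f}]".rjust(10))
    return "\n".join(lines)


@dataclass(frozen=True)
class VarianceComponents:
    """Mixed-model variance components feeding the heritability formula.

    Vg: genotype variance; Vgl: genotype-by-location interaction variance;
    Ve: environment (residual) variance — all in squared trait units.
    L locations, R repetitions.
    """

    Vg: float
    Vgl: float
    Ve: float
    L: int = 1
    R: int = 1

    def __post_init__(self):
        if min(self.Vg, self.Vgl, self.Ve) < 0:
            raise ValueError("variance components must be non-negative")
        if self.L < 1 or self.R < 1:
            raise ValueError("L and R must be >= 1")


def heritability_h2(vc: VarianceComponents) -> float:
    """Generalized (broad-sense) heritability
    H^2 = Vg / (Vg + Vgl/L + Ve/(L*R)), in [0, 1]."""
    denom = vc.Vg + vc.Vgl / vc.L + vc.Ve / (vc.L * vc.R)
    if denom == 0.0:
        raise Leaf3DError("heritability undefined: all variance components are zero")
    return vc.Vg / denom
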