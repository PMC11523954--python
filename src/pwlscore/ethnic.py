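"""Cross-population effect of a signed SNP panel from minor-allele frequencies.

A simple prediction score assigns each SNP a sign c ∈ {+1, −1} and adds
c × (minor-allele count) to the score. Under Hardy–Weinberg equilibrium at
minor-allele frequency p, the expected contribution of one SNP in a
population is

    c · 2p(1 − p) + 2c · p²  =  2cp

(heterozygotes carry one minor allele, minor homozygotes two). Summing over
a panel gives the expected shift of the score attributable to genetic
background in that population — a crude but transparent way to compare how
a genotype-driven score would transfer across ancestries. Frequencies are
taken from a 1000 Genomes-style per-population table; a panel for 19
prostate-cancer SNPs (16 with frequencies available) ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SchemaError

__all__ = [
    "AlleleFrequencyPanel",
    "EffectEstimate",
    "snp_effect",
    "population_effect",
    "read_frequency_table",
    "load_default_panel",
]

DEFAULT_POPULATIONS = ("SAS", "AFR", "EUR", "AMR", "EAS")


@dataclass(frozen=True)
class AlleleFrequencyPanel:
    """Per-SNP signed coefficients plus per-population minor-allele frequencies.

    ``table`` has one row per SNP with columns ``snp_id``, ``coefficient``
    (±1) and one float column per population; unavailable frequencies are
    NaN and are excluded from effect sums.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"snp_id", "coefficient"}
        if not required.issubset(self.table.columns):
            raise SchemaError(f"panel needs columns {sorted(required)}")
        coef = self.table["coefficient"]
        if not coef.isin([-1, 1]).all():
            raise InvalidParameterError("coefficients must be +1 or -1")
        for pop in self.populations:
            freqs = self.table[pop].dropna()
            if ((freqs < 0) | (freqs > 0.5)).any():
                raise InvalidParameterError(
                    f"minor-allele frequencies in column {pop!r} must lie in [0, 0.5]"
                )

    @property
    def populations(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("snp_id", "coefficient")]

    def __len__(self) -> int:
        return len(self.table)

    def n_available(self, population: str) -> int:
        return int(self.table[population].notna().sum())


@dataclass(frozen=True)
class EffectEstimate:
    population: str
    effect: float
    n_snps_used: int

    @property
    def rounded(self) -> float:
        """Display value, 2 decimals (internal sums stay unrounded)."""
        return round(self.effect, 2)


def snp_effect(coefficient: float, maf: float) -> float:
    """Expected score contribution of one SNP under HWE.

    Computes ``c·2p(1−p) + 2c·p²``; algebraically this equals ``2cp`` but
    the two-term HWE form is kept because it makes the genotype-class
    weighting explicit (heterozygote once, minor homozygote twice).
    """
    if not 0.0 <= maf <= 0.5:
        raise InvalidParameterError(f"minor-allele frequency {maf} outside [0, 0.5]")
    return coefficient * 2.0 * maf * (1.0 - maf) + 2.0 * coefficient * maf**2


def population_effect(panel: AlleleFrequencyPanel, population: str) -> EffectEstimate:
    """Sum of per-SNP effects over the SNPs with an available frequency."""
    if population not in panel.populations:
        raise SchemaError(
            f"unknown population {population!r}; panel has {panel.populations}"
        )
    sub = panel.table[["coefficient", population]].dropna(subset=[population])
    if sub.empty:
        raise InvalidParameterError(
            f"no SNP in the panel has an available frequency for {population!r}"
        )
    total = float(
        sum(snp_effect(c, p) for c, p in zip(sub["coefficient"], sub[population]))
    )
    return EffectEstimate(population=population, effect=total, n_snps_used=len(sub))


def read_frequency_table(path: str | Path) -> AlleleFrequencyPanel:
    """Read a delimited SNP/coefficient/frequency table (``NA`` allowed).

    The file must be tab- or comma-delimited with a header row naming
    ``snp_id``, ``coefficient`` and one column per population. Malformed
    rows raise with the offending line number.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise SchemaError(f"{path}: empty frequency table")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    header = text.splitlines()[0].split(sep)
    n_cols = len(header)
    for lineno, line in enumerate(text.splitlines()[1:], start=2):
        if len(line.split(sep)) != n_cols:
            raise SchemaError(f"{path}:{lineno}: expected {n_cols} fields")
    df = pd.read_csv(path, sep=sep, na_values=["NA"])
    pop_cols = [c for c in df.columns if c not in ("snp_id", "coefficient")]
    for lineno, (_, row) in enumerate(df.iterrows(), start=2):
        if row["coefficient"] not in (-1, 1):
            raise SchemaError(
                f"{path}:{lineno}: coefficient must be +1 or -1, got {row['coefficient']}"
            )
        for pop in pop_cols:
            p = row[pop]
            if pd.notna(p) and not 0.0 <= p <= 0.5:
                raise SchemaError(
                    f"{path}:{lineno}: frequency {p} in column {pop!r} outside [0, 0.5]"
                )
    return AlleleFrequencyPanel(table=df)


def load_default_panel() -> AlleleFrequencyPanel:
    """The packaged 19-SNP castration-resistance panel with 1000 Genomes MAFs."""
    ref = resources.files("pwlscore").joinpath("data/allele_frequency_panel.tsv")
    with resources.as_file(ref) as path:
        return read_frequency_table(path)


def population_effects(
    panel: AlleleFrequencyPanel, populations: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tabulate :func:`population_effect` over several populations."""
    pops = list(populations) if populations is not None else panel.populations
    rows = []
    for pop in pops:
        est = population_effect(panel, pop)
        rows.append(
            {
                "population": pop,
                "effect": est.effect,
                "effect_2dp": est.rounded,
                "n_snps_used": est.n_snps_used,
            }
        )
    return pd.DataFrame(rows)
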