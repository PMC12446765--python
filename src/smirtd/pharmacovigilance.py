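"""Proportional reporting ratio (PRR) statistics for spontaneous-report data.

For a target drug and target ADR, with report counts

    NTT  reports of the target ADR for the target drug
    NAT  all ADR reports for the target drug
    NTA  target-ADR reports for all other drugs
    NAA  all ADR reports for all other drugs

the disproportionality signal is PRR = (NTT/NAT) / (NTA/NAA), with the 95%
confidence interval

    exp( ln(PRR) +/- 1.96 * sqrt(1/NTT - 1/NAT + 1/NTA - 1/NAA) ).

PRR > 1 suggests the ADR is reported disproportionately often for the drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .corpus import canonicalize

__all__ = ["ReportCounts", "PRRResult", "compute_prr", "filter_prr", "prr_table"]


@dataclass(frozen=True)
class ReportCounts:
    NTT: float
    NAT: float
    NTA: float
    NAA: float

    def __post_init__(self) -> None:
        if min(self.NTT, self.NAT, self.NTA, self.NAA) < 0:
            raise ValueError("report counts must be non-negative")
        if self.NTT > self.NAT or self.NTA > self.NAA:
            raise ValueError("need NTT <= NAT and NTA <= NAA")


@dataclass(frozen=True)
class PRRResult:
    prr: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.prr <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")


def compute_prr(counts: ReportCounts, haldane_correction: bool = False) -> PRRResult:
    """Point estimate and 95% CI.  Any zero count makes the PRR undefined and
    raises, unless the opt-in Haldane +0.5 continuity correction is requested."""
    ntt, nat, nta, naa = counts.NTT, counts.NAT, counts.NTA, counts.NAA
    if min(ntt, nat, nta, naa) == 0:
        if not haldane_correction:
            raise ValueError(
                "PRR undefined with a zero report count "
                "(pass haldane_correction=True for the +0.5 adjustment)"
            )
        ntt, nat, nta, naa = ntt + 0.5, nat + 0.5, nta + 0.5, naa + 0.5
    prr = (ntt / nat) / (nta / naa)
    se = math.sqrt(1.0 / ntt - 1.0 / nat + 1.0 / nta - 1.0 / naa)
    half = 1.96 * se
    return PRRResult(prr, math.exp(math.log(prr) - half), math.exp(math.log(prr) + half))


def filter_prr(
    table: pd.DataFrame,
    threshold: float = 1.0,
    exclude_smiles: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Apply the external-validation filters to a drug/PRR table.

    ``table`` needs columns drug_id, smiles, prr.  Keeps rows with
    ``prr >= threshold``, deduplicates by canonical SMILES (first occurrence
    wins), and drops drugs whose canonical SMILES appears in
    ``exclude_smiles`` (the curated training compounds).
    """
    df = table.copy()
    df["_canonical"] = [canonicalize(s) for s in df["smiles"]]
    df = df[df["prr"] >= threshold]
    df = df.drop_duplicates(subset="_canonical", keep="first")
    if exclude_smiles:
        banned = {canonicalize(s) for s in exclude_smiles}
        df = df[~df["_canonical"].isin(banned)]
    return df.drop(columns="_canonical").reset_index(drop=True)


def prr_table(counts_table: pd.DataFrame, haldane_correction: bool = False) -> pd.DataFrame:
    """Add prr, ci_low, ci_high columns to a table with NTT/NAT/NTA/NAA."""
    out = counts_table.copy()
    results = [
        compute_prr(ReportCounts(r.NTT, r.NAT, r.NTA, r.NAA), haldane_correction)
        for r in out.itertuples(index=False)
    ]
    out["prr"] = [r.prr for r in results]
    out["ci_low"] = [r.ci_low for r in results]
    out["ci_high"] = [r.ci_high for r in results]
    return out
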