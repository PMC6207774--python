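"""Drug-target enrichment and cell-line IC50 contrasts.

Two checks of a signature's pharmacological relevance: (1) are druggable
genes overrepresented inside the signature relative to the network universe
(one-sided Fisher exact test); (2) are cell lines more sensitive — lower
IC50 — to drugs that target signature genes than to all other drugs (Welch
two-sided t-test on natural-log IC50, per cell line)?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["target_overrepresentation", "ic50_contrast", "EnrichmentResult"]


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple          # ((a, b), (c, d)): signature/non-signature x targeted/untargeted
    odds_ratio: float     # NaN when a margin is degenerate
    p_value: float
    degenerate: bool


def target_overrepresentation(signature, drug_targets: pd.DataFrame, universe) -> EnrichmentResult:
    """One-sided (greater) Fisher exact test for targeted genes in a signature.

    The test is at the gene level: a gene counts as targeted if at least one
    drug lists it. Targets are intersected with ``universe``; the signature
    must be a subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sig = set(signature.genes) if hasattr(signature, "genes") else set(signature)
    if not sig <= uni:
        raise ValueError("signature is not a subset of the universe")
    targeted = set(drug_targets["gene"]) & uni
    a = len(sig & targeted)
    b = len(sig - targeted)
    c = len((uni - sig) & targeted)
    d = len((uni - sig) - targeted)
    degenerate = (a + c == len(uni)) or (b + d == len(uni))
    if degenerate:
        return EnrichmentResult(table=((a, b), (c, d)), odds_ratio=float("nan"), p_value=1.0, degenerate=True)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(table=((a, b), (c, d)), odds_ratio=float(odds), p_value=float(p), degenerate=False)


def ic50_contrast(
    ic50: pd.DataFrame,
    drug_targets: pd.DataFrame,
    signature,
    min_group: int = 2,
) -> pd.DataFrame:
    """Per-cell-line Welch t contrast of ln IC50: signature drugs vs others.

    A drug is a signature drug if it targets at least one signature gene.
    Cell lines with fewer than ``min_group`` drugs in either group are
    skipped with a warning. Returns one row per tested cell line with columns
    n_signature_drugs, n_other_drugs, mean_log_diff (signature minus other;
    negative = more sensitive to signature drugs) and p_value.
    """
    sig = set(signature.genes) if hasattr(signature, "genes") else set(signature)
    sig_drugs = set(drug_targets.loc[drug_targets["gene"].isin(sig), "drug_id"])
    rows = []
    skipped = []
    for cl, sub in ic50.groupby("cell_line"):
        is_sig = sub["drug_id"].isin(sig_drugs)
        a = np.log(sub.loc[is_sig, "ic50"].to_numpy(dtype=float))
        b = np.log(sub.loc[~is_sig, "ic50"].to_numpy(dtype=float))
        if len(a) < min_group or len(b) < min_group:
            skipped.append(cl)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((cl, len(a), len(b), float(a.mean() - b.mean()), float(p)))
    if skipped:
        warnings.warn(f"skipped {len(skipped)} cell line(s) with < {min_group} drugs in a group", stacklevel=2)
    return pd.DataFrame(
        rows, columns=["cell_line", "n_signature_drugs", "n_other_drugs", "mean_log_diff", "p_value"]
    )
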