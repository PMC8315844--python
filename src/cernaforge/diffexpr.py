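"""TPM quantification, control-vs-treated testing, and threshold screening.

The screening semantics follow the common two-condition design: a per-feature
log2 fold change (treated over control, on mean TPM with a pseudocount) and a
two-sided p-value, thresholded at strict |log2FC| > 2 and p < 0.05 by
default. The group-comparison test is a Welch two-sample t-test on
log2(TPM + pseudocount); tools like Ballgown fill the same role on real data
but their internal model is not reproduced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import ExpressionBundle, RNA_CLASSES


@dataclass
class DERecord:
    feature_id: str
    rna_class: str
    mean_control: float
    mean_treated: float
    log2fc: float
    pvalue: float
    direction: str = "ns"  # up / down / ns


@dataclass
class DESets:
    """Screened up/down feature IDs per RNA class, with the thresholds used."""

    up: dict[str, list[str]] = field(default_factory=dict)
    down: dict[str, list[str]] = field(default_factory=dict)
    lfc_cut: float = 2.0
    p_cut: float = 0.05

    def members(self, rna_class: str) -> set[str]:
        return set(self.up.get(rna_class, [])) | set(self.down.get(rna_class, []))

    def direction_of(self, rna_class: str, feature_id: str) -> str:
        if feature_id in self.up.get(rna_class, []):
            return "up"
        if feature_id in self.down.get(rna_class, []):
            return "down"
        return "ns"


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to 1e6 per sample.

    rate_i = count_i / (length_i / 1000); TPM_i = rate_i / sum_j rate_j * 1e6.
    Every column of the result sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing lengths for features: {missing}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])[:5]
        raise ValueError(f"non-positive lengths for features: {bad}")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total expression: {list(zero.index)}")
    return rate.div(totals, axis=1) * 1e6


def test_differential(bundle: ExpressionBundle, pseudocount: float = 1.0) -> list[DERecord]:
    """Welch t-test on log2(TPM + pseudocount), per feature, all classes.

    log2fc is computed on condition-mean TPM with the same pseudocount, so
    all-zero features get log2fc = 0 rather than an undefined ratio. Features
    with zero variance in both groups get p = 1 when the means are equal
    (no evidence) and p = 0 when they differ (the noiseless limit).
    """
    ctrl = bundle.samples("control")
    trt = bundle.samples("treated")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 replicates per condition")

    records: list[DERecord] = []
    for cls in RNA_CLASSES:
        if cls not in bundle.counts:
            continue
        tpm = compute_tpm(bundle.counts[cls], bundle.lengths[cls])
        a = tpm[ctrl].to_numpy()
        b = tpm[trt].to_numpy()
        mean_c = a.mean(axis=1)
        mean_t = b.mean(axis=1)
        lfc = np.log2(mean_t + pseudocount) - np.log2(mean_c + pseudocount)

        la = np.log2(a + pseudocount)
        lb = np.log2(b + pseudocount)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        # degenerate: zero variance in both groups -> nan from Welch
        degenerate = np.isnan(pvals)
        if degenerate.any():
            equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
            pvals = np.where(degenerate, np.where(equal, 1.0, 0.0), pvals)

        for fid, mc, mt, fc, p in zip(tpm.index, mean_c, mean_t, lfc, pvals):
            records.append(DERecord(feature_id=fid, rna_class=cls,
                                    mean_control=float(mc), mean_treated=float(mt),
                                    log2fc=float(fc), pvalue=float(p)))
    return records


def screen_de(records: list[DERecord], lfc_cut: float = 2.0,
              p_cut: float = 0.05) -> DESets:
    """Screen with strict thresholds: up iff log2fc > lfc_cut and p < p_cut.

    Boundary values (|log2fc| == lfc_cut or p == p_cut) are not significant.
    Directions are written back onto the records; set membership is ordered
    by feature_id for determinism.
    """
    sets = DESets(lfc_cut=lfc_cut, p_cut=p_cut)
    for rec in records:
        if rec.pvalue < p_cut and rec.log2fc > lfc_cut:
            rec.direction = "up"
        elif rec.pvalue < p_cut and rec.log2fc < -lfc_cut:
            rec.direction = "down"
        else:
            rec.direction = "ns"
    classes = sorted({r.rna_class for r in records})
    for cls in classes:
        sets.up[cls] = sorted(r.feature_id for r in records
                              if r.rna_class == cls and r.direction == "up")
        sets.down[cls] = sorted(r.feature_id for r in records
                                if r.rna_class == cls and r.direction == "down")
    return sets


def desets_from_truth(bundle: ExpressionBundle) -> DESets:
    """DE sets taken from the generator's planted labels rather than the screen.

    Useful for testing downstream stages (consensus, triplets, enrichment)
    in isolation from the sampling noise of the statistical screen.
    """
    sets = DESets()
    for cls, labels in bundle.truth_de.items():
        sets.up[cls] = sorted(labels.index[labels == "up"])
        sets.down[cls] = sorted(labels.index[labels == "down"])
    return sets


def records_to_frame(records: list[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in records],
        columns=["feature_id", "rna_class", "mean_control", "mean_treated",
                 "log2fc", "pvalue", "direction"],
    )


def frame_to_records(df: pd.DataFrame) -> list[DERecord]:
    return [DERecord(**{k: row[k] for k in
                        ("feature_id", "rna_class", "mean_control", "mean_treated",
                         "log2fc", "pvalue", "direction")})
            for _, row in df.iterrows()]
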