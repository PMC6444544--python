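"""TPM expression profiling across organs and treatments, and qRT-PCR folds.

The expression container is a genes x samples TPM table where every sample
carries (organ, treatment) metadata; organs default to leaf/root and
treatments to control plus five stress/hormone applications (H2O2, heat
shock, ABA, salicylic acid, PEG).  Response calls are descriptive
fold-change categories (up / down / insensitive / not_expressed) against the
within-organ control, not differential-expression tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ORGANS = ("leaf", "root")
TREATMENTS = ("control", "H2O2", "HS", "ABA", "SA", "PEG")
CALLS = ("up", "down", "insensitive", "not_expressed")


@dataclass
class ExpressionMatrix:
    """Genes x (organ, treatment) TPM values.

    ``data`` is a DataFrame indexed by gene with a 2-level column MultiIndex
    (organ, treatment).  Values must be finite and nonnegative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex) or \
                self.data.columns.nlevels != 2:
            raise ValueError("columns must be a 2-level (organ, treatment) index")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("TPM values must be finite")
        if (vals < 0).any():
            raise ValueError("TPM values must be nonnegative")

    @property
    def organs(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(1)))

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Read a TSV whose column headers are ``organ:treatment``."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split(":", 1)) for c in df.columns],
            names=("organ", "treatment"),
        )
        return cls(df)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.columns = [f"{o}:{t}" for o, t in out.columns]
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class ResponseCall:
    gene: str
    organ: str
    treatment: str
    call: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


@dataclass(frozen=True)
class CtRecord:
    """qRT-PCR Ct quadruple for one gene/treatment against a calibrator."""

    gene: str
    treatment: str
    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    @property
    def ddct(self) -> float:
        return (self.ct_target_treated - self.ct_reference_treated) - \
               (self.ct_target_control - self.ct_reference_control)


def log2_heatmap_matrix(m: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Heatmap transform: every TPM value becomes log2(TPM + pseudocount)."""
    vals = m.data.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative TPM")
    return pd.DataFrame(
        np.log2(vals + pseudocount), index=m.data.index, columns=m.data.columns
    )


def call_responses(
    m: ExpressionMatrix,
    fc_threshold: float = 2.0,
    expression_floor: float = 1.0,
    ratio_pseudocount: float = 0.01,
    control: str = "control",
) -> list[ResponseCall]:
    """Categorise every gene x organ x non-control treatment.

    up: (treat+eps)/(ctrl+eps) >= threshold and treat >= floor;
    down: ratio <= 1/threshold and ctrl >= floor;
    not_expressed: both below the floor; otherwise insensitive.
    """
    calls: list[ResponseCall] = []
    eps = ratio_pseudocount
    for organ in m.organs:
        if (organ, control) not in m.data.columns:
            raise ValueError(f"no {control!r} sample for organ {organ!r}")
        ctrl = m.data[(organ, control)]
        for treatment in m.treatments:
            if treatment == control or (organ, treatment) not in m.data.columns:
                continue
            treat = m.data[(organ, treatment)]
            for gene in m.data.index:
                c, t = float(ctrl[gene]), float(treat[gene])
                fc = (t + eps) / (c + eps)
                if c < expression_floor and t < expression_floor:
                    call = "not_expressed"
                elif fc >= fc_threshold and t >= expression_floor:
                    call = "up"
                elif fc <= 1.0 / fc_threshold and c >= expression_floor:
                    call = "down"
                else:
                    call = "insensitive"
                calls.append(ResponseCall(gene, organ, treatment, call, fc))
    return calls


def aggregate_by_group(
    calls: list[ResponseCall],
    labels: dict[str, str],
    matrix: ExpressionMatrix | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Summarise calls per group x (organ, treatment).

    ``labels`` maps gene -> group (class or subclass).  Output columns:
    pct_up, pct_down, n_genes, all_not_expressed flag, and mean log2(TPM+1)
    when the matrix is supplied.  Every gene in ``calls`` must be labelled.
    """
    unlabeled = sorted({c.gene for c in calls} - set(labels))
    if unlabeled:
        raise ValueError(f"unlabeled genes: {unlabeled}")
    rows = []
    frame = pd.DataFrame(
        [(labels[c.gene], c.organ, c.treatment, c.call, c.gene) for c in calls],
        columns=["group", "organ", "treatment", "call", "gene"],
    )
    log2m = log2_heatmap_matrix(matrix, pseudocount) if matrix is not None else None
    for (group, organ, treatment), grp in frame.groupby(
        ["group", "organ", "treatment"], sort=True
    ):
        n = len(grp)
        row = {
            "group": group, "organ": organ, "treatment": treatment,
            "n_genes": n,
            "pct_up": 100.0 * (grp["call"] == "up").sum() / n,
            "pct_down": 100.0 * (grp["call"] == "down").sum() / n,
            "all_not_expressed": bool((grp["call"] == "not_expressed").all()),
        }
        if log2m is not None:
            row["mean_log2"] = float(
                log2m.loc[grp["gene"], (organ, treatment)].mean()
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index(["group", "organ", "treatment"])


def ddct_fold(ct: CtRecord) -> float:
    """Relative expression by the 2^-ddCt method; the calibrator gives 1."""
    for v in (ct.ct_target_treated, ct.ct_reference_treated,
              ct.ct_target_control, ct.ct_reference_control):
        if v is None or not np.isfinite(v):
            raise ValueError("all four Ct values must be present and finite")
    return float(2.0 ** (-ct.ddct))
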