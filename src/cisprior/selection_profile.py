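"""Selective-constraint classification of lead SNPs.

Conservation is read from GERP-style rejected-substitution scores
(RS >= 0: substitution deficit, i.e. evolutionarily conserved; RS < 0:
substitution surplus, i.e. positively selected in mammalian evolution;
RS at or above ``rs_strong`` marks strong negative selection, and
RS/NR = 1 marks positions with no observed substitution at all).
Population-specific signals come from Tajima's D (values above
``td_strong`` suggest balancing selection in the focal population) and
from derived allele frequencies (DAF and its cross-population
difference). A variant with RS above ``rs_strong`` *and* TD above
``td_strong`` is under joint strong constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from cisprior.core_io import PipelineConfig, SelectionRecord

__all__ = ["SelectionClass", "classify_selection", "selection_counts"]

_REL_TOL = 1e-9  # RS/NR == 1 tested as |RS - NR| <= tol * max(1, |NR|)


@dataclass(frozen=True)
class SelectionClass:
    """Per-variant constraint flags. Population flags are None when the
    corresponding statistic is missing."""

    rsid: str
    conserved: bool                   # RS >= 0
    strongly_conserved: bool          # RS >= rs_strong
    positively_selected: bool         # RS < 0
    strongly_positive: bool           # RS <= -rs_strong
    fully_conserved: bool             # RS/NR = 1 (no observed substitution)
    balancing: Optional[bool]         # TD > td_strong
    td_sign: Optional[str]            # 'positive' | 'negative' | 'zero'
    high_daf: Optional[bool]          # DAF >= daf_high
    daf_elevated: Optional[bool]      # dDAF > 0
    joint_strong: Optional[bool]      # RS > rs_strong and TD > td_strong


def classify_selection(
    rec: SelectionRecord, config: Optional[PipelineConfig] = None
) -> SelectionClass:
    """Deterministically classify one selection record.

    Missing TD/DAF statistics yield None sub-flags, never exceptions.
    Note the asymmetry on the strong-constraint flags: the RS-only
    strong class is inclusive (RS >= rs_strong) while the joint RS-and-TD
    class is strict on both (RS > rs_strong and TD > td_strong).
    """
    cfg = config or PipelineConfig()
    conserved = rec.rs_score >= 0.0
    fully = abs(rec.rs_score - rec.nr_score) <= _REL_TOL * max(1.0, abs(rec.nr_score))
    if rec.td is None:
        td_sign = balancing = joint = None
    else:
        td_sign = "positive" if rec.td > 0 else ("negative" if rec.td < 0 else "zero")
        balancing = rec.td > cfg.td_strong
        joint = rec.rs_score > cfg.rs_strong and rec.td > cfg.td_strong
    return SelectionClass(
        rsid=rec.rsid,
        conserved=conserved,
        strongly_conserved=rec.rs_score >= cfg.rs_strong,
        positively_selected=not conserved,
        strongly_positive=rec.rs_score <= -cfg.rs_strong,
        fully_conserved=fully,
        balancing=balancing,
        td_sign=td_sign,
        high_daf=None if rec.daf is None else rec.daf >= cfg.daf_high,
        daf_elevated=None if rec.delta_daf is None else rec.delta_daf > 0,
        joint_strong=joint,
    )


def selection_counts(
    records: Sequence[SelectionRecord], config: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """Tally every constraint flag over a set of records.

    Returns a table with one row per flag: count, the denominator it was
    evaluated against, and the percentage. Conservation flags are counted
    over all records; population flags only over records where the
    statistic is present (these denominators are reported, since real
    retrievals drop a few variants).
    """
    classes = [classify_selection(r, config) for r in records]
    n_all = len(classes)
    with_td = [c for c in classes if c.td_sign is not None]
    with_daf = [c for c in classes if c.high_daf is not None]
    with_ddaf = [c for c in classes if c.daf_elevated is not None]
    with_joint = [c for c in classes if c.joint_strong is not None]

    def row(flag, count, denom):
        pct = 100.0 * count / denom if denom else 0.0
        return {"flag": flag, "count": count, "n": denom, "percent": round(pct, 2)}

    rows = [
        row("conserved", sum(c.conserved for c in classes), n_all),
        row("strongly_conserved", sum(c.strongly_conserved for c in classes), n_all),
        row("positively_selected", sum(c.positively_selected for c in classes), n_all),
        row("strongly_positive", sum(c.strongly_positive for c in classes), n_all),
        row("fully_conserved", sum(c.fully_conserved for c in classes), n_all),
        row("td_positive", sum(c.td_sign == "positive" for c in with_td), len(with_td)),
        row("td_negative", sum(c.td_sign == "negative" for c in with_td), len(with_td)),
        row("balancing", sum(bool(c.balancing) for c in with_td), len(with_td)),
        row("high_daf", sum(bool(c.high_daf) for c in with_daf), len(with_daf)),
        row("daf_elevated", sum(bool(c.daf_elevated) for c in with_ddaf), len(with_ddaf)),
        row("joint_strong", sum(bool(c.joint_strong) for c in with_joint), len(with_joint)),
    ]
    return pd.DataFrame(rows, columns=["flag", "count", "n", "percent"])
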