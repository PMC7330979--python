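"""Wild-versus-mutant contact assessment.

For every mutant, the seven contact types are counted in both structures and
their signed differences tabulated.  The headline per-type *accuracy* is the
fraction of mutants whose count increased or stayed equal (delta >= 0); a
strict-increase accuracy is reported alongside for transparency, and for
hydrophobic contacts the complementary "reduced or kept" accuracy (delta <= 0)
is also given, since proposals substitute polar pairs and are expected to
shed hydrophobic contacts.

The significance test is the classic paired t-test on per-structure totals,
one-tailed; the direction is an explicit argument because stabilising designs
may be tested for either an increase or a decrease depending on the type.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .errors import DegenerateTestError
from .interactions import CONTACT_TYPES, classify_contacts, contact_delta


def evaluate_proposals(wild, mutants, mutant_ids=None):
    """Contact-count table for a wild structure and its mutants.

    Returns ``(table, summary)``: one row per mutant and contact type with
    wild count, mutant count and delta; and one summary row per type with the
    accuracies defined above.  Empty mutant list gives empty frames.
    """
    cols = ["mutant", "contact_type", "wild_count", "mutant_count", "delta"]
    if not mutants:
        return (pd.DataFrame(columns=cols),
                pd.DataFrame(columns=["contact_type", "n_mutants",
                                      "accuracy_increase_or_kept",
                                      "accuracy_strict_increase",
                                      "accuracy_reduced_or_kept"]))
    wild_profile = classify_contacts(wild)
    ids = list(mutant_ids) if mutant_ids is not None else [m.id for m in mutants]
    rows = []
    for mid, mutant in zip(ids, mutants):
        delta = contact_delta(wild_profile, classify_contacts(mutant))
        for t in CONTACT_TYPES:
            rows.append({"mutant": mid, "contact_type": t,
                         "wild_count": wild_profile[t],
                         "mutant_count": wild_profile[t] + delta[t],
                         "delta": delta[t]})
    table = pd.DataFrame(rows, columns=cols)
    summary_rows = []
    for t in CONTACT_TYPES:
        deltas = table.loc[table["contact_type"] == t, "delta"]
        summary_rows.append({
            "contact_type": t,
            "n_mutants": len(deltas),
            "accuracy_increase_or_kept": float((deltas >= 0).mean()),
            "accuracy_strict_increase": float((deltas > 0).mean()),
            "accuracy_reduced_or_kept": float((deltas <= 0).mean()),
        })
    return table, pd.DataFrame(summary_rows)


def paired_one_tailed_ttest(wild_counts, mutant_counts, direction: str = "greater"):
    """Paired one-tailed t-test on per-structure contact totals.

    ``direction="greater"`` tests whether mutant counts exceed wild counts
    (``"less"`` the opposite).  Returns ``(t, p)``; zero-variance differences
    raise :class:`DegenerateTestError` rather than reporting a fake p-value.
    """
    if direction not in ("greater", "less"):
        raise DegenerateTestError(f"direction must be 'greater' or 'less', got {direction!r}")
    wild = list(wild_counts)
    mut = list(mutant_counts)
    if len(wild) != len(mut):
        raise DegenerateTestError("paired test needs equal-length count lists")
    if len(wild) < 2:
        raise DegenerateTestError("paired test needs at least two pairs")
    diffs = [m - w for m, w in zip(mut, wild)]
    if max(diffs) == min(diffs):
        raise DegenerateTestError("differences have zero variance; t-test undefined")
    res = stats.ttest_rel(mut, wild, alternative=direction)
    return float(res.statistic), float(res.pvalue)
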