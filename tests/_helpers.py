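"""Shared test builders."""

import pandas as pd

from rppa_triscore.scoring import ScoreSet


def build_score_set(cond_entries, n_proteins=40):
    """ScoreSet whose condition scores realize prescribed per-condition sums.

    ``cond_entries`` maps (cell_line, condition) to the desired integer sum;
    entries are laid down as -1/+1 scores across proteins and the two
    replicate columns of that condition.
    """
    lines = {line for line, _ in cond_entries}
    cols = []
    for line in sorted(lines):
        for rep in (1, 2):
            for cond in ("hypoxia", "normoxia"):
                cols.append((line, rep, cond))
    if not cols:
        cols = [("X", 1, "hypoxia"), ("X", 1, "normoxia")]
    cond_df = pd.DataFrame(
        0.0, index=[f"p{i}" for i in range(n_proteins)],
        columns=pd.MultiIndex.from_tuples(cols, names=["cell_line", "replicate", "treatment"]),
    )
    for (line, cond), total in cond_entries.items():
        sign = 1.0 if total >= 0 else -1.0
        remaining = abs(int(total))
        for rep in (1, 2):
            take = min(remaining, n_proteins)
            if take:
                cond_df.loc[cond_df.index[:take], (line, rep, cond)] = sign
            remaining -= take
        assert remaining == 0, "requested sum exceeds capacity"
    col_df = pd.DataFrame(
        0.0, index=cond_df.index,
        columns=pd.MultiIndex.from_tuples(
            sorted({(l, r) for l, r, _ in cols}), names=["cell_line", "replicate"]
        ),
    )
    return ScoreSet(effect="treatment", scores=col_df, condition_scores=cond_df,
                    thresholds=(0.0, 0.0))
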