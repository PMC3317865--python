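"""Factorial design construction and sample-sheet handling.

The experiment crosses cell lines (two lineages: high-grade glioma and
adenocarcinoma) with culture medium (2D monolayer vs 3D spheroid), oxygen
treatment (normoxia 21% O2 vs relative hypoxia 1% O2) and biological
replicate.  A full crossing of 11 lines x 2 media x 2 treatments x 2
replicates yields 88 samples; the study design used here drops three
replicates that failed, leaving 85.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

GLIOMA_LINES: tuple[str, ...] = ("U87", "U251", "SNB19", "LNZ308", "LN229")
ADENO_LINES: tuple[str, ...] = ("MCF7", "MDA231", "MDA468", "MiaPaCa", "OVCAR5", "SKOV3")

MEDIA: tuple[str, str] = ("2D", "3D")
TREATMENTS: tuple[str, str] = ("normoxia", "hypoxia")
LINEAGES: tuple[str, str] = ("glioma", "adenocarcinoma")

#: the three design cells whose second replicate failed in the study
DEFAULT_DROPPED: tuple[tuple[str, str, str, int], ...] = (
    ("LNZ308", "3D", "normoxia", 2),
    ("LNZ308", "3D", "hypoxia", 2),
    ("U87", "3D", "normoxia", 2),
)

SHEET_COLUMNS = ["sample_id", "cell_line", "lineage", "medium", "treatment", "replicate"]


def sample_id(cell_line: str, medium: str, treatment: str, replicate: int) -> str:
    """Synthesize the canonical sample identifier for a design cell."""
    return f"{cell_line}_{medium}_{treatment}_r{replicate}"


def _line_names(n: int, defaults: Sequence[str], prefix: str) -> list[str]:
    if n <= len(defaults):
        return list(defaults[:n])
    extra = [f"{prefix}{i:02d}" for i in range(len(defaults) + 1, n + 1)]
    return list(defaults) + extra


def build_design(
    n_glioma: int = 5,
    n_adeno: int = 6,
    n_replicates: int = 2,
    dropped: Iterable[tuple[str, str, str, int]] = (),
    glioma_lines: Sequence[str] | None = None,
    adeno_lines: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the full factorial sample sheet minus dropped replicates.

    Parameters
    ----------
    n_glioma, n_adeno
        Number of cell lines per lineage.  Default names follow the study
        panel (U87, U251, ...); extra lines get generic names.
    n_replicates
        Biological replicates per design cell.
    dropped
        Design cells to remove, as ``(cell_line, medium, treatment,
        replicate)`` tuples.  A key outside the design raises ``KeyError``.

    Returns
    -------
    DataFrame with columns ``sample_id, cell_line, lineage, medium,
    treatment, replicate``, ordered by (cell line, medium, treatment,
    replicate) with cell lines in panel order (gliomas first).
    """
    if n_glioma < 0 or n_adeno < 0 or n_replicates < 0:
        raise ValueError("counts must be non-negative")
    gl = list(glioma_lines) if glioma_lines is not None else _line_names(n_glioma, GLIOMA_LINES, "GL")
    ac = list(adeno_lines) if adeno_lines is not None else _line_names(n_adeno, ADENO_LINES, "AC")
    rows = []
    for line, lineage in [(l, "glioma") for l in gl] + [(l, "adenocarcinoma") for l in ac]:
        for medium in MEDIA:
            for treatment in TREATMENTS:
                for rep in range(1, n_replicates + 1):
                    rows.append((sample_id(line, medium, treatment, rep), line, lineage, medium, treatment, rep))
    sheet = pd.DataFrame(rows, columns=SHEET_COLUMNS)

    drop_ids = []
    valid = set(sheet["sample_id"])
    for key in dropped:
        sid = sample_id(*key) if not isinstance(key, str) else key
        if sid not in valid:
            raise KeyError(f"dropped key not in design: {key!r}")
        drop_ids.append(sid)
    sheet = sheet[~sheet["sample_id"].isin(drop_ids)].reset_index(drop=True)
    return sheet


def validate_sheet(sheet: pd.DataFrame) -> None:
    """Check sample-sheet invariants; raise ``ValueError`` on violation."""
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup}")
    cells = sheet[["cell_line", "medium", "treatment", "replicate"]]
    if cells.duplicated().any():
        raise ValueError("duplicate design cell (cell_line, medium, treatment, replicate)")
    per_line = sheet.groupby("cell_line")["lineage"].nunique()
    bad = per_line[per_line > 1]
    if len(bad):
        raise ValueError(f"lineage not constant within cell line(s): {list(bad.index)}")
    bad_med = set(sheet["medium"]) - set(MEDIA)
    bad_trt = set(sheet["treatment"]) - set(TREATMENTS)
    if bad_med or bad_trt:
        raise ValueError(f"unknown factor levels: media {bad_med}, treatments {bad_trt}")


def normalize_sheet_order(sheet: pd.DataFrame) -> pd.DataFrame:
    """Deterministic row order: cell line (alphabetical), medium, treatment, replicate."""
    med = pd.Categorical(sheet["medium"], categories=MEDIA, ordered=True)
    trt = pd.Categorical(sheet["treatment"], categories=TREATMENTS, ordered=True)
    out = sheet.assign(_m=med.codes, _t=trt.codes)
    out = out.sort_values(["cell_line", "_m", "_t", "replicate"], kind="mergesort")
    return out.drop(columns=["_m", "_t"]).reset_index(drop=True)


def read_sample_sheet(path, dialect: str = "tab") -> pd.DataFrame:
    sep = {"tab": "\t", "comma": ","}[dialect]
    sheet = pd.read_csv(path, sep=sep)
    validate_sheet(sheet)
    return normalize_sheet_order(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path, dialect: str = "tab") -> None:
    sep = {"tab": "\t", "comma": ","}[dialect]
    sheet.to_csv(path, sep=sep, index=False)


# --- antibody panel -----------------------------------------------------

#: antibody labels printed in the study that we reuse as panel labels
_NAMED_TARGETS = [
    "FAK", "AKT", "Src", "GSK3ab", "TSC2", "p38", "NFkBp65",
    "ATRIP", "ATR", "beta-catenin", "BCL-XL", "cyclinB1", "Egr-1", "HIF-1a",
    "NCKIPSD", "4EBP1_S65", "c-Myc", "SMAD3_S423", "S6_S235", "S6_S240",
    "BAX", "caspase7", "c-JUN", "MEK1", "PARP1-cleaved", "VEGFR2",
    "Stat3_T727", "COX2", "collagen-VI", "Src_Y416",
]

#: targets spotted twice under different labels (3 duplicates -> 124 labels)
DUPLICATE_TARGETS = ("BCL-XL", "collagen-VI", "Src_Y416")


def default_panel(n_distinct: int = 121, duplicates: Sequence[str] = DUPLICATE_TARGETS) -> pd.DataFrame:
    """Antibody panel: ``n_distinct`` targets plus duplicate labels.

    Returns a DataFrame with columns ``label`` (unique slide label) and
    ``target`` (the protein measured).  With the defaults this gives
    121 distinct targets carried by 124 labels (three targets are spotted
    in duplicate under a second label).
    """
    targets = _NAMED_TARGETS + [f"AB{i:03d}" for i in range(1, n_distinct - len(_NAMED_TARGETS) + 1)]
    targets = targets[:n_distinct]
    rows = [{"label": t, "target": t} for t in targets]
    for dup in duplicates:
        if dup not in targets:
            raise KeyError(f"duplicate target not in panel: {dup}")
        rows.append({"label": f"{dup}_dup", "target": dup})
    return pd.DataFrame(rows)


def panel_summary(panel: pd.DataFrame) -> dict:
    """Label/target bookkeeping for a panel DataFrame."""
    n_labels = panel["label"].nunique()
    n_targets = panel["target"].nunique()
    return {
        "n_labels": n_labels,
        "n_distinct_targets": n_targets,
        "n_duplicates": n_labels - n_targets,
    }
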