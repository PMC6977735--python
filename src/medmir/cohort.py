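"""Clinical table parsing and cohort descriptive statistics.

The clinical schema carries one row per patient pair: ages at the primary
and recurrent surgeries, sex, tumor localization, resection margin codes
(R0 microscopically negative, R1 microscopically positive, R2
macroscopically positive, Rx unknown/not assessed) for both surgeries, time
to recurrence in years, and optionally the per-pair DMR count.

Quartiles default to the (n+1)-based "exclusive" interpolation, which
matches how clinical interquartile ranges are conventionally reported;
other interpolation rules are selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

MARGIN_CODES = ("R0", "R1", "R2", "Rx")
SEXES = ("female", "male")

COLUMNS = [
    "pair_id",
    "age_primary",
    "age_recurrent",
    "sex",
    "localization",
    "margin_primary",
    "margin_recurrent",
    "time_to_recurrence_years",
]

DEFAULT_EXTREMITY_SITES = frozenset({"upper leg", "lower leg"})
DEFAULT_RETRO_SITES = frozenset({"retroperitoneal"})


def quantile(values, q: float, method: str = "exclusive") -> float:
    """Quantile of a numeric list.

    ``exclusive``: rank h = q*(n+1) with linear interpolation, h clipped to
    [1, n].  Any other method name is passed through to numpy.quantile
    (e.g. ``linear`` for the (n-1)-based rule, ``inclusive`` maps to it).
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        raise InputError("quantile of empty list")
    if not (0 <= q <= 1):
        raise InputError("q must lie in [0, 1]")
    if method == "exclusive":
        n = v.size
        h = np.clip(q * (n + 1), 1, n)
        lo = int(np.floor(h))
        frac = h - lo
        if lo >= n:
            return float(v[-1])
        return float(v[lo - 1] + frac * (v[lo] - v[lo - 1]))
    np_method = "linear" if method == "inclusive" else method
    return float(np.quantile(v, q, method=np_method))


def read_clinical(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"pair_id": str})
    return validate_clinical(table)


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"clinical table lacks columns: {missing}")
    if table["pair_id"].duplicated().any():
        raise InputError("duplicate pair_id")
    for col in ("margin_primary", "margin_recurrent"):
        bad = ~table[col].isin(MARGIN_CODES)
        if bad.any():
            raise InputError(
                f"unknown margin code in {col}: {sorted(table.loc[bad, col].unique())}"
            )
    bad_sex = ~table["sex"].isin(SEXES)
    if bad_sex.any():
        raise InputError(f"unknown sex: {sorted(table.loc[bad_sex, 'sex'].unique())}")
    if (table["time_to_recurrence_years"] <= 0).any():
        raise InputError("time_to_recurrence_years must be > 0")
    if (table["age_recurrent"] < table["age_primary"]).any():
        raise InputError("age_recurrent < age_primary")
    return table


def load_reference_cohort() -> pd.DataFrame:
    """The packaged 27-pair well-differentiated liposarcoma cohort table."""
    with resources.as_file(
        resources.files("medmir.data").joinpath("clinical_wdlps.tsv")
    ) as p:
        return read_clinical(p)


@dataclass
class CohortSummary:
    n_pairs: int
    median_age_primary: float
    age_primary_iqr: tuple[float, float]
    median_time_to_recurrence: float
    time_to_recurrence_iqr: tuple[float, float]
    sex_counts: dict[str, int] = field(default_factory=dict)
    localization_counts: dict[str, int] = field(default_factory=dict)
    margin_counts_primary: dict[str, int] = field(default_factory=dict)
    margin_counts_recurrent: dict[str, int] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            f"pairs: {self.n_pairs}",
            "median age at primary surgery: "
            f"{self.median_age_primary:g} (IQR {self.age_primary_iqr[0]:g}-"
            f"{self.age_primary_iqr[1]:g})",
            "median time to recurrence (years): "
            f"{self.median_time_to_recurrence:g} (IQR "
            f"{self.time_to_recurrence_iqr[0]:g}-{self.time_to_recurrence_iqr[1]:g})",
            "sex: " + ", ".join(f"{k}={v}" for k, v in sorted(self.sex_counts.items())),
            "localization: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.localization_counts.items())),
            "primary margins: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.margin_counts_primary.items())),
            "recurrent margins: "
            + ", ".join(
                f"{k}={v}" for k, v in sorted(self.margin_counts_recurrent.items())
            ),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_pairs", self.n_pairs),
            ("median_age_primary", self.median_age_primary),
            ("age_primary_q1", self.age_primary_iqr[0]),
            ("age_primary_q3", self.age_primary_iqr[1]),
            ("median_time_to_recurrence", self.median_time_to_recurrence),
            ("time_to_recurrence_q1", self.time_to_recurrence_iqr[0]),
            ("time_to_recurrence_q3", self.time_to_recurrence_iqr[1]),
        ]
        for prefix, d in [
            ("sex", self.sex_counts),
            ("localization", self.localization_counts),
            ("margin_primary", self.margin_counts_primary),
            ("margin_recurrent", self.margin_counts_recurrent),
        ]:
            rows += [(f"{prefix}_{k}", v) for k, v in sorted(d.items())]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def summarize_cohort(
    table: pd.DataFrame,
    extremity_sites=DEFAULT_EXTREMITY_SITES,
    retro_sites=DEFAULT_RETRO_SITES,
    quantile_method: str = "exclusive",
) -> CohortSummary:
    """Descriptive statistics of a clinical table.

    Localizations are grouped into extremity / retroperitoneum / other by
    (case-insensitive) membership in the supplied site sets; margin counts
    are tallied separately for the primary and recurrent surgeries.
    """
    table = validate_clinical(table)
    extremity = {s.lower() for s in extremity_sites}
    retro = {s.lower() for s in retro_sites}

    def loc_class(site: str) -> str:
        s = site.lower()
        if s in extremity:
            return "extremity"
        if s in retro:
            return "retroperitoneum"
        return "other"

    ages = table["age_primary"].to_numpy(dtype=float)
    ttr = table["time_to_recurrence_years"].to_numpy(dtype=float)
    qm = quantile_method
    loc_counts = table["localization"].map(loc_class).value_counts().to_dict()
    for key in ("extremity", "retroperitoneum", "other"):
        loc_counts.setdefault(key, 0)
    summary = CohortSummary(
        n_pairs=len(table),
        median_age_primary=quantile(ages, 0.5, qm),
        age_primary_iqr=(quantile(ages, 0.25, qm), quantile(ages, 0.75, qm)),
        median_time_to_recurrence=quantile(ttr, 0.5, qm),
        time_to_recurrence_iqr=(quantile(ttr, 0.25, qm), quantile(ttr, 0.75, qm)),
        sex_counts=table["sex"].value_counts().to_dict(),
        localization_counts=loc_counts,
        margin_counts_primary=table["margin_primary"].value_counts().to_dict(),
        margin_counts_recurrent=table["margin_recurrent"].value_counts().to_dict(),
    )
    return summary
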