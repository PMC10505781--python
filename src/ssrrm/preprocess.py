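"""Data edits applied before model fitting.

Two edit families, mirroring routine practice for national longitudinal
evaluations:

* marker edits -- drop SNPs with call rate below a floor or minor allele
  frequency below a floor, then mean-impute the surviving missing dosages;
* record edits -- drop records deviating more than ``sd_mult`` standard
  deviations from their age-group mean, then keep only animals with at
  least ``min_records`` records including one before ``early_age`` and one
  after ``late_age`` months (so every retained animal informs the whole
  trajectory).

Each filter returns the edited container plus a :class:`FilterReport` whose
counts can be compared against an independent recount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypePanel, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["FilterReport", "filter_snps", "filter_phenotypes"]


@dataclass
class FilterReport:
    """Counts removed per rule; write with :meth:`to_tsv`."""

    counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, key: str) -> int:
        return self.counts[key]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.counts.items()), columns=["rule", "count"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FilterReport":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["rule"], df["count"])))


def filter_snps(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
) -> tuple[GenotypePanel, FilterReport]:
    """Apply call-rate and MAF edits; impute remaining missing dosages.

    Call rate is checked first; MAF (on non-missing dosages) is checked on
    the survivors. Frequencies are recomputed on the retained set and the
    remaining missing dosages are replaced by their expectation ``2 p_o``.
    """
    call = panel.call_rate()
    freq = panel.observed_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    pass_call = call >= call_rate_min
    pass_maf = np.nan_to_num(maf, nan=-1.0) >= maf_min
    keep = pass_call & pass_maf
    if not keep.any():
        raise ValueError("all SNPs removed by the marker edits")
    report = FilterReport(
        {
            "snp_total": panel.n_snp,
            "snp_removed_call_rate": int((~pass_call).sum()),
            "snp_removed_maf": int((pass_call & ~pass_maf).sum()),
            "snp_retained": int(keep.sum()),
        }
    )
    filtered = panel.subset_snps(keep)
    filtered.allele_freq = filtered.observed_frequencies()
    # mean imputation: store expected dosages as the panel's float view
    # (integer dosages stay as-is; downstream code calls imputed_dosages()).
    return filtered, report


def filter_phenotypes(
    table: PhenotypeTable,
    sd_mult: float = 5.0,
    min_records: int = 3,
    early_age: int = 10,
    late_age: int = 30,
) -> tuple[PhenotypeTable, FilterReport]:
    """Apply the record edits: 5-SD outliers per age, then animal eligibility.

    Step 1 removes records whose value deviates from the grand age-group
    mean by more than ``sd_mult`` standard deviations (age groups with fewer
    than 2 records are skipped with a log message -- no SD is defined).
    Step 2 keeps animals that, after step 1, have at least ``min_records``
    records including one at an age < ``early_age`` and one at an age >
    ``late_age``.
    """
    if len(table) == 0:
        raise ValueError("phenotype table is empty")
    df = table.frame
    keep = np.ones(len(df), dtype=bool)
    for age, grp in df.groupby("age_months"):
        if len(grp) < 2:
            logger.warning(
                "age group %s has %d record(s); outlier edit skipped", age, len(grp)
            )
            continue
        mu = grp["value"].mean()
        sd = grp["value"].std(ddof=1)
        if sd == 0:
            continue
        out = np.abs(grp["value"] - mu) > sd_mult * sd
        keep[grp.index[out]] = False
    n_outliers = int((~keep).sum())
    df1 = df.loc[keep]

    per_animal = df1.groupby("animal")
    n_rec = per_animal.size()
    has_early = per_animal["age_months"].min() < early_age
    has_late = per_animal["age_months"].max() > late_age
    ok_count = n_rec >= min_records
    eligible = ok_count & has_early & has_late
    keep_animals = set(eligible.index[eligible])
    df2 = df1[df1["animal"].isin(keep_animals)].reset_index(drop=True)

    report = FilterReport(
        {
            "records_total": len(df),
            "records_removed_outlier": n_outliers,
            "animals_total": int(df["animal"].nunique()),
            "animals_removed_min_records": int((~ok_count).sum()),
            "animals_removed_no_early_record": int((ok_count & ~has_early).sum()),
            "animals_removed_no_late_record": int(
                (ok_count & has_early & ~has_late).sum()
            ),
            "animals_retained": len(keep_animals),
            "records_retained": len(df2),
        }
    )
    return PhenotypeTable(df2), report
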