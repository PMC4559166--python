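"""Mutation-fixation timelines and clone genotype summaries.

Population Sanger traces distinguish three states per mutation and
timepoint: no mutant peak (absent), two peaks (polymorphic — mutant and
wild-type coexist), or only the mutant peak (fixed).  The classifier
emulates that readout with two frequency thresholds chosen from typical
chromatogram minor-peak sensitivity: a minor allele below ~20 % is invisible,
above ~80 % the wild-type peak disappears.  No monotonicity is assumed —
frequencies may fall again (clonal interference).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

STATUSES = ("absent", "polymorphic", "fixed")


def classify_allele_status(frequency: float, lower: float = 0.2,
                           upper: float = 0.8) -> str:
    """Classify a population allele frequency into absent/polymorphic/fixed.

    absent if f < lower; polymorphic if lower <= f < upper; fixed if
    f >= upper.  The three statuses partition [0, 1].
    """
    if not 0.0 <= frequency <= 1.0:
        raise InvalidArgumentError("frequency must be in [0, 1]")
    if not 0.0 < lower < upper <= 1.0:
        raise InvalidArgumentError("need 0 < lower < upper <= 1")
    if frequency < lower:
        return "absent"
    if frequency < upper:
        return "polymorphic"
    return "fixed"


def build_mutation_timeline(frequency_table: pd.DataFrame, lower: float = 0.2,
                            upper: float = 0.8) -> pd.DataFrame:
    """Classify a (mutation x timepoint) frequency table cell-by-cell.

    Returns a status table of the same shape plus ``first_detected`` and
    ``first_fixed`` columns (the earliest timepoint at which the mutation is
    non-absent / fixed; NaN if never).  Missing cells yield the explicit
    status 'missing', never a silent fill.
    """
    statuses = pd.DataFrame(index=frequency_table.index,
                            columns=frequency_table.columns, dtype=object)
    for m in frequency_table.index:
        for t in frequency_table.columns:
            f = frequency_table.loc[m, t]
            if pd.isna(f):
                statuses.loc[m, t] = "missing"
            else:
                statuses.loc[m, t] = classify_allele_status(float(f), lower,
                                                            upper)
    first_detected = []
    first_fixed = []
    for m in statuses.index:
        row = statuses.loc[m]
        det = [t for t in statuses.columns
               if row[t] in ("polymorphic", "fixed")]
        fix = [t for t in statuses.columns if row[t] == "fixed"]
        first_detected.append(det[0] if det else np.nan)
        first_fixed.append(fix[0] if fix else np.nan)
    out = statuses.copy()
    out["first_detected"] = first_detected
    out["first_fixed"] = first_fixed
    return out


def genotype_clone_summary(clone_genotypes: pd.DataFrame,
                           loci: Optional[Sequence[str]] = None
                           ) -> pd.DataFrame:
    """Count clones per genotype signature over the given loci.

    ``clone_genotypes`` is clones x loci with 0/1 presence calls; the
    signature is the tuple of presence flags in ``loci`` order.  Counts
    always sum to the number of clones.
    """
    loci = list(loci) if loci is not None else list(clone_genotypes.columns)
    missing = [l for l in loci if l not in clone_genotypes.columns]
    if missing:
        raise InvalidArgumentError(f"unscored loci: {missing}")
    if clone_genotypes[loci].isna().any().any():
        raise InvalidArgumentError("every clone must be scored at every locus")
    if len(clone_genotypes) == 0:
        return pd.DataFrame(columns=[*loci, "n_clones"])
    grouped = (clone_genotypes[loci].astype(int)
               .groupby(loci, sort=True).size().reset_index(name="n_clones"))
    assert grouped["n_clones"].sum() == len(clone_genotypes)
    return grouped


def sample_clone_genotypes(frequencies: dict, n_clones: int,
                           seed: int = 0) -> pd.DataFrame:
    """Draw clone genotypes from independent per-locus population frequencies.

    A helper for round-trip checks: summarising the sampled clones recovers
    each frequency to within binomial error.
    """
    rng = np.random.default_rng(seed)
    data = {locus: (rng.random(n_clones) < f).astype(int)
            for locus, f in frequencies.items()}
    return pd.DataFrame(data,
                        index=[f"clone{i + 1:03d}" for i in range(n_clones)])
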