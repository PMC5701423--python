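"""Beta-value computation, QC filtering cascade, and M-value transform.

The methylation level at a CpG is summarized as
``beta = M / (U + M + 100)`` from the methylated (M) and unmethylated (U)
signal intensities; the +100 offset regularizes low-intensity probes, so
beta lies in [0, 1). QC removes probes sequentially: (1) any missing
value, (2) SNP-overlapping probes, (3) sex-chromosome probes, (4) probes
whose detection p-value exceeds 0.05 in at least 75% of samples. A probe
is counted at the first rule it trips, so per-step removal counts are
well defined. For clustering, beta is mapped to the variance-stabilized
M-value scale via the logit-2 transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import IntensityData
from .utils import log


@dataclass
class BetaMatrix:
    """Beta values (probes x samples) with group and pairing labels."""

    beta: pd.DataFrame
    sample_groups: pd.Series  # sample_id -> "tumor" | "normal"
    pair_ids: pd.Series  # sample_id -> pair label

    def __post_init__(self):
        self.sample_groups = self.sample_groups.reindex(self.beta.columns)
        self.pair_ids = self.pair_ids.reindex(self.beta.columns)

    @property
    def tumor_samples(self):
        return self.beta.columns[(self.sample_groups == "tumor").to_numpy()]

    @property
    def normal_samples(self):
        return self.beta.columns[(self.sample_groups == "normal").to_numpy()]

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.beta.loc[probe_ids], self.sample_groups, self.pair_ids)


@dataclass
class MValueMatrix:
    m_value: pd.DataFrame
    epsilon: float


@dataclass
class FilterReport:
    """Sequential QC bookkeeping: step names, removals, and running totals."""

    initial_count: int
    steps: list = field(default_factory=list)  # (name, removed, retained_after)

    def add(self, name: str, removed: int) -> None:
        prev = self.steps[-1][2] if self.steps else self.initial_count
        self.steps.append((name, int(removed), prev - int(removed)))

    @property
    def removed_counts(self):
        return [s[1] for s in self.steps]

    @property
    def final_retained(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "removed", "retained"])


def beta_matrix_from_sheet(beta: pd.DataFrame, sample_sheet: pd.DataFrame) -> BetaMatrix:
    sheet = sample_sheet.reindex(beta.columns)
    return BetaMatrix(beta, sheet["group"], sheet["pair_id"])


def compute_beta(intensities: IntensityData, sample_sheet: pd.DataFrame | None = None):
    """Elementwise beta = M / (U + M + 100); missing entries stay NaN.

    Returns a plain DataFrame when no sample sheet is given, otherwise a
    :class:`BetaMatrix` carrying group/pair labels.
    """
    m = intensities.meth
    u = intensities.unmeth
    if (m < 0).any().any() or (u < 0).any().any():
        raise ValueError("signal intensities must be nonnegative")
    beta = m / (u + m + 100.0)
    if sample_sheet is None:
        return beta
    return beta_matrix_from_sheet(beta, sample_sheet)


def qc_filter(
    beta: BetaMatrix,
    intensities: IntensityData,
    manifest: pd.DataFrame,
    detection_alpha: float = 0.05,
    detection_sample_fraction: float = 0.75,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the four-step QC cascade in its fixed order.

    Steps: missing values, SNP probes, X/Y probes, detection failures
    (detection p > ``detection_alpha`` in >= ``detection_sample_fraction``
    of samples). Each probe is removed at the first step it trips.
    """
    probes = beta.beta.index
    if not probes.isin(manifest.index).all():
        raise ValueError("manifest does not cover all probes in the beta matrix")
    man = manifest.loc[probes]
    report = FilterReport(initial_count=len(probes))

    keep = pd.Series(True, index=probes)

    missing = intensities.missing_mask.loc[probes].any(axis=1) | beta.beta.isna().any(axis=1)
    hit = missing & keep
    report.add("missing_values", hit.sum())
    keep &= ~hit

    snp = man["snp_flag"].astype(bool)
    hit = snp & keep
    report.add("snp_probes", hit.sum())
    keep &= ~hit

    xy = man["chromosome"].isin(["chrX", "chrY", "X", "Y"])
    hit = xy & keep
    report.add("xy_probes", hit.sum())
    keep &= ~hit

    det = intensities.detection_p.loc[probes]
    fail_frac = (det > detection_alpha).mean(axis=1)
    detfail = fail_frac >= detection_sample_fraction
    hit = detfail & keep
    report.add("detection_failure", hit.sum())
    keep &= ~hit

    if not keep.any():
        log.warning("QC filtering removed every probe")
    filtered = beta.subset_probes(probes[keep.to_numpy()])
    return filtered, report


def beta_to_mvalue(beta, epsilon: float = 1e-6):
    """M-value = log2(beta / (1 - beta)) with beta clamped to
    [epsilon, 1 - epsilon] so the transform stays finite."""
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    frame = beta.beta if isinstance(beta, BetaMatrix) else beta
    clamped = frame.clip(lower=epsilon, upper=1.0 - epsilon)
    m = np.log2(clamped / (1.0 - clamped))
    return MValueMatrix(m_value=m, epsilon=epsilon)


def mvalue_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of the logit-2 transform: beta = 2^m / (2^m + 1)."""
    p = np.power(2.0, m)
    return p / (p + 1.0)
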