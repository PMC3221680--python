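"""Analysis thresholds and panel definitions.

All cutoffs used by the scoring, paired-drift and array modules live in a
single frozen :class:`ThresholdConfig` so that a run's thresholds can be
echoed into its outputs and overridden in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

#: CpG island methylator phenotype (CIMP) marker panel.
DEFAULT_CIMP_PANEL: tuple[str, ...] = ("MINT1", "MINT2", "MINT31", "p16", "p14", "MLH1")

#: The 13 candidate loci assayed by bisulfite-pyrosequencing.
CANDIDATE_LOCI: tuple[str, ...] = (
    "MINT1", "MINT2", "MINT31", "MLH1", "p16", "p14",
    "TIMP3", "CDH1", "CDH13", "THBS1", "MGMT", "HPP1", "ERalpha",
)


@dataclass(frozen=True)
class ThresholdConfig:
    """Cutoffs for methylation calling and paired comparison.

    Parameters
    ----------
    density_cutoff : float
        Percent methylation density above which (strictly) a locus is called
        methylated. Default 15.
    fold_cutoff : float
        Fold change (max/min of the two densities) above which (strictly) a
        primary-metastasis pair shows a meaningful drift, provided at least
        one density exceeds ``density_cutoff``. Default 2.
    cimp_min_markers : int
        Minimum number of methylated panel markers for a CIMP-positive call.
        Default 2.
    cimp_panel : tuple of str
        Marker loci defining CIMP.
    mcam_log2_cutoff : float
        Normalized log2 ratio above which (strictly) an array gene is called
        hypermethylated. Default 1.0 (~2-fold).
    metachronous_min_months : float
        Minimum interval, in months, between resection of the primary tumor
        and resection of the liver metastasis for the metastasis to count as
        metachronous (closed bound). Default 12.
    ci_level : float
        Confidence level for normal-approximation intervals. Default 0.95.
    """

    density_cutoff: float = 15.0
    fold_cutoff: float = 2.0
    cimp_min_markers: int = 2
    cimp_panel: tuple[str, ...] = DEFAULT_CIMP_PANEL
    mcam_log2_cutoff: float = 1.0
    metachronous_min_months: float = 12.0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        for name in ("density_cutoff", "fold_cutoff", "mcam_log2_cutoff",
                     "metachronous_min_months"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.cimp_min_markers <= 0:
            raise ValueError("cimp_min_markers must be > 0")
        if len(self.cimp_panel) == 0:
            raise ValueError("cimp_panel must be non-empty")
        if self.cimp_min_markers > len(self.cimp_panel):
            raise ValueError(
                f"cimp_min_markers ({self.cimp_min_markers}) exceeds panel size "
                f"({len(self.cimp_panel)})"
            )
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be a fraction in (0, 1)")


DEFAULT_CONFIG = ThresholdConfig()
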