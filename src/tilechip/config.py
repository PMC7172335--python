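"""Pipeline-wide tunable parameters.

Every distance, threshold, and window used by the analysis stages lives in
:class:`PipelineConfig` so that a single object documents (and overrides)
the numeric conventions of the whole pipeline.  Defaults follow the
published tiling-array protocol this package re-implements; fields that the
protocol leaves open are marked below.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    """All numeric knobs of the tiling-array analysis.

    Distances are in base pairs unless noted.  ``probe_alpha`` and the
    neighbor/run distances implement the per-array neighborhood peak-calling
    model; the profile windows implement the boundary/TSS meta-profiles and
    Pol II region tests.
    """

    # --- peak calling (neighborhood model) ---
    neighbor_max_gap: int = 1000     # max distance for two probes to count as neighbors
    probe_alpha: float = 0.05        # averaged-p threshold for probe significance
    peak_probe_gap: int = 300        # max gap between consecutive significant probes in a peak
    min_sig_probes: int = 4          # min significant probes per peak

    # --- overlap / annotation rules ---
    overlap_slack: int = 500         # "within +/- 500 bp" insulator-overlap rule
    promoter_upstream: int = 200     # promoter = 200 bp upstream of the TSS
    dpg_max_tss_gap: int = 1000      # divergent pair: TSS-to-TSS distance cap
    dpg_peak_flank: int = 500        # DPG bound: peak within 500 bp downstream of a TSS
    tad_boundary_slack: int = 5000   # peak counts as at a TAD boundary within 5 kb

    # --- profiles ---
    boundary_flank: int = 10000      # domain-boundary profiles span +/- 10 kb
    center_flank: int = 5000         # domain-center profiles span +/- 5 kb
    domain_window: int = 10          # sliding-window length for domain profiles (1 bp step)
    paused_region: tuple[int, int] = (-30, 300)   # Pol II paused region, TSS-relative
    gene_body_start: int = 1000      # gene body starts 1 kb downstream of the TSS
    min_gene_len: int = 1000         # genes shorter than this are excluded from Pol II analysis
    polII_span: tuple[int, int] = (-2000, 5000)   # Pol II meta-profile span, TSS-relative
    polII_window: int = 100          # Pol II profile sliding-window length
    polII_smooth: int = 900          # moving-average width for profile display
    k4_interval: tuple[int, int] = (0, 2000)      # H3K4me3 per-gene test interval, TSS-relative
    k27_interval: tuple[int, int] = (200, 2200)   # H3K27me3 per-gene test interval, TSS-relative
    fdr_alpha: float = 0.05          # BH-adjusted significance cutoff

    # --- permutation enrichment ---
    n_perm: int = 1000               # shuffles per enrichment test

    # --- motif scanning ---
    motif_promoter_flank: int = 500  # promoter windows are TSS +/- 500 bp
    pwm_p: float = 0.01              # PWM scan p-value threshold
    consensus_p: float = 0.001       # IUPAC consensus scan p-value threshold
    markov_order: int = 2            # background Markov order (full-genome fits support up to 7)

    # --- smoothing / misc ---
    pseudomedian_span: int = 3       # pseudomedian window, in probes
    rng_seed: int = 0

    # genes excluded from divergent-pair analysis (e.g. histone-cluster ids)
    dpg_exclude_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("neighbor_max_gap", "peak_probe_gap", "overlap_slack",
                     "promoter_upstream", "dpg_max_tss_gap", "dpg_peak_flank",
                     "tad_boundary_slack", "boundary_flank", "center_flank",
                     "gene_body_start", "min_gene_len", "motif_promoter_flank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("probe_alpha", "fdr_alpha", "pwm_p", "consensus_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_sig_probes < 1:
            raise ValueError("min_sig_probes must be >= 1")
        if self.domain_window < 1 or self.polII_window < 1:
            raise ValueError("window lengths must be >= 1")
        if self.pseudomedian_span < 1 or self.pseudomedian_span % 2 == 0:
            raise ValueError("pseudomedian_span must be odd and >= 1")
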