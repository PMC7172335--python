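"""Shared study conditions for the numbered analysis scripts.

Every script regenerates the same synthetic study from these settings
(regeneration takes well under a second), so each driver is
self-contained and the whole analysis is reproducible from any entry
point.  Bulky track exports go to scratch/; result tables go to results/.
"""

from pathlib import Path

from tilechip.simulate import simulate_annotation, simulate_chip_tracks

STUDY_SEED = 20
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

# study genome: two 300 kb chromosome arms, 60 genes, 40% in divergent pairs
ANNOTATION = dict(n_chrom=2, chrom_len=300_000, n_genes=60, dpg_fraction=0.4)
# tracks: 33 bp probe grid, SNR-4 factor peaks, half-depleted H3K27me3
# domains (plateau 2), two-regime Pol II genes, noise sd 0.3
TRACKS = dict(spacing=33, peak_snr=4.0, domain_depletion=0.5, noise_sd=0.3,
              peak_width=200, domain_plateau=2.0)


def load_study():
    genome, genes, truth = simulate_annotation(seed=STUDY_SEED, **ANNOTATION)
    tracks = simulate_chip_tracks(genome, genes, truth,
                                  seed=STUDY_SEED + 1, **TRACKS)
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return genome, genes, truth, tracks
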