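"""Generate the synthetic study and export its inputs in standard formats.

Writes the gene annotation (GFF3), planted peak/domain truth (BED), and
the probe signal tracks (wiggle, under scratch/ — they are bulky) so the
downstream stages can be demonstrated from files as well as in memory.
"""

import pandas as pd

from study import RESULTS, SCRATCH, load_study
from tilechip.core_io import write_genes, write_intervals, write_signal


def main():
    genome, genes, truth, tracks = load_study()
    write_genes(genes, RESULTS / "genes.gff3")
    write_intervals(truth.peaks["factor"], RESULTS / "true_peaks.bed")
    write_intervals((d.interval for d in truth.domains),
                    RESULTS / "true_domains.bed")
    pd.DataFrame(truth.dpg_pairs,
                 columns=["gene_minus", "gene_plus", "tss_gap"]).to_csv(
        RESULTS / "true_dpgs.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.polII_regime.items()),
                 columns=["gene_id", "regime"]).to_csv(
        RESULTS / "true_polii_regimes.tsv", sep="\t", index=False)
    for (mark, cond), track in tracks.items():
        write_signal(track, SCRATCH / f"{mark}_{cond}.wig")
    print(f"genome: {len(genome.chroms)} chromosomes, "
          f"{sum(genome.entries.values()):,} bp")
    print(f"genes: {len(genes)} ({len(truth.dpg_pairs)} divergent pairs)")
    print(f"planted: {len(truth.peaks['factor'])} factor peaks, "
          f"{len(truth.domains)} H3K27me3 domains")
    print(f"tracks: {len(tracks)} written to {SCRATCH}/")


if __name__ == "__main__":
    main()
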