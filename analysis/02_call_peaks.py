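"""Call factor peaks with the neighborhood model and score the recovery.

Per-probe p-values come from the robust empirical null (median/MAD of the
array); peaks are runs of >= 4 significant probes within 300 bp, where a
probe is significant if its averaged p with an adjacent probe (<= 1 kb)
is below 0.05.
"""

import pandas as pd

from study import RESULTS, load_study
from tilechip.core_io import write_intervals
from tilechip.peaks import call_peaks, peaks_to_bed_score, probe_significance


def main():
    _, _, truth, tracks = load_study()
    sig = probe_significance(tracks[("factor", "control")])
    peaks = call_peaks(sig)
    true_ivs = list(truth.peaks["factor"])
    tp = sum(any(pk.interval.overlaps(t) for t in true_ivs) for pk in peaks)
    fn = sum(not any(pk.interval.overlaps(t) for pk in peaks)
             for t in true_ivs)

    bed = [pk.interval.__class__(pk.interval.chrom, pk.interval.start,
                                 pk.interval.end, pk.interval.name,
                                 float(peaks_to_bed_score(pk.score)), ".")
           for pk in peaks]
    write_intervals(bed, RESULTS / "called_peaks.bed")
    pd.DataFrame([{"peak": pk.interval.name, "chrom": pk.interval.chrom,
                   "start": pk.interval.start, "end": pk.interval.end,
                   "n_sig": pk.n_sig, "score": round(pk.score, 4)}
                  for pk in peaks]).to_csv(
        RESULTS / "called_peaks.tsv", sep="\t", index=False)

    print(f"called {len(peaks)} peaks against {len(true_ivs)} planted sites")
    print(f"sensitivity {tp / (tp + fn):.3f}, "
          f"precision {tp / len(peaks):.3f}")
    print(f"wrote {RESULTS / 'called_peaks.bed'} and .tsv sidecar")


if __name__ == "__main__":
    main()
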