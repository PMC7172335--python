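"""Pseudomedian-smooth the signal tracks for browser export.

Applies the span-3 Hodges-Lehmann pseudomedian (median of Walsh averages
per 3-probe window) to each track and writes the smoothed wiggles to
scratch/; a summary of the noise reduction goes to results/.
"""

import numpy as np
import pandas as pd

from study import RESULTS, SCRATCH, load_study
from tilechip.core_io import write_signal
from tilechip.smooth import pseudomedian_smooth


def main():
    _, _, _, tracks = load_study()
    rows = []
    for (mark, cond), track in sorted(tracks.items()):
        smoothed = pseudomedian_smooth(track, span=3)
        write_signal(smoothed, SCRATCH / f"{mark}_{cond}_pm3.wig")
        raw_sd = np.concatenate(
            [track.values(c)[:, 0] for c in track.chroms]).std()
        sm_sd = np.concatenate(
            [smoothed.values(c)[:, 0] for c in smoothed.chroms]).std()
        rows.append({"mark": mark, "condition": cond,
                     "raw_sd": round(float(raw_sd), 4),
                     "smoothed_sd": round(float(sm_sd), 4)})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "smoothing_summary.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"smoothed wiggles under {SCRATCH}/")


if __name__ == "__main__":
    main()
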