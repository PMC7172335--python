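"""Scan promoter windows for the YAACKG and TTSSSSS consensus motifs.

Promoter windows (TSS +/- 500 bp) are simulated with 60% of windows
carrying one planted YAACKG instance.  Consensus scans run both strands
at the p < 0.001 match-probability threshold; a PWM built from the
consensus is also scanned at p < 0.01 with exact DP p-values.
"""

import numpy as np
import pandas as pd

from study import RESULTS, SCRATCH, STUDY_SEED, load_study
from tilechip.motif import (Pwm, fit_background, scan_consensus, scan_pwm)
from tilechip.simulate import _IUPAC, simulate_sequences


def consensus_pwm(consensus, strength=0.97):
    rows = []
    for code in consensus:
        allowed = _IUPAC[code]
        row = np.full(4, (1 - strength) / (4 - len(allowed))
                      if len(allowed) < 4 else 0.25)
        for b in allowed:
            row["ACGT".index(b)] = strength / len(allowed)
        rows.append(row / row.sum())
    return Pwm(np.array(rows), label=consensus)


def main():
    _, genes, truth, _ = load_study()
    seqs, plants = simulate_sequences(genes, "YAACKG", plant_rate=0.6,
                                      gc=0.4, seed=STUDY_SEED + 5)
    bg = fit_background(seqs, order=2, pseudocount=0.1)

    rows = []
    for consensus in ("YAACKG", "TTSSSSS"):
        hits = scan_consensus(seqs, consensus, bg, p_thresh=0.001)
        for h in hits:
            rows.append({"motif": consensus, "seq_id": h.seq_id,
                         "position": h.position, "strand": h.strand,
                         "score_bits": round(h.score, 3), "p": h.p})
        print(f"{consensus}: {len(hits)} consensus hits in "
              f"{len(seqs)} windows")
    pd.DataFrame(rows).to_csv(RESULTS / "motif_hits.tsv", sep="\t",
                              index=False)
    pwm_hits = scan_pwm(seqs, consensus_pwm("YAACKG"), bg, p_thresh=0.01)
    pd.DataFrame([{"seq_id": h.seq_id, "position": h.position,
                   "strand": h.strand, "score_bits": round(h.score, 3),
                   "p": h.p} for h in pwm_hits]).to_csv(
        SCRATCH / "pwm_hits.tsv", sep="\t", index=False)

    found = {(h["seq_id"], h["position"], h["strand"])
             for h in rows if h["motif"] == "YAACKG"}
    recovered = sum((gid, pos, strand) in found
                    for gid, (pos, strand) in plants.items())
    print(f"planted YAACKG instances recovered: {recovered}/{len(plants)}")
    print(f"PWM scan at p < 0.01: {len(pwm_hits)} hits")


if __name__ == "__main__":
    main()
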