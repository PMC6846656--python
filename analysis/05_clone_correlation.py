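#!/usr/bin/env python
"""Processivity signature: per-clone distribution and correlation length.

From the per-clone consensus calls, builds the binary clone x C-site
matrix per strand, then measures: the mutations-per-clone histogram
(singly vs multiply mutated fractions), the fraction of mutation pairs
falling in a 10-nt window, the distance-dependent correlation C(d) of
the normalised mutation covariance, and the exponential correlation
length L from C(d) = exp(-d/L) -- with a column-permutation null for
contrast.

Finding: the engagement-tract generative model leaves a clear positive
short-range correlation that decays with distance and vanishes under
column permutation, the same qualitative signature used to argue for
processive deamination within a stalled transcription bubble.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from aidmds import clones
from aidmds.sequences import DEFAULT_REGIONS, ReferencePair

OUT = Path("results/analysis")
RNG_SEED = 20250925


def main() -> None:
    ref = ReferencePair.from_fasta(OUT / "library" / "reference.fasta")
    ref.regions = dict(DEFAULT_REGIONS)
    report = {}
    for strand in ("NTS", "TS"):
        calls = pd.read_csv(OUT / f"clone_calls_{strand}.tsv", sep="\t")
        calls = calls[(calls["ref"] == "C") & (calls["alt"] == "T")]
        calls["coord"] = [ref.duplex_coord(strand, int(p)) for p in calls["pos"]]
        coords = [ref.duplex_coord(strand, p) for p in ref.c_positions(strand)]
        mat = clones.CloneMutationMatrix.from_calls(calls, coords, strand)
        hist = clones.mutations_per_clone(mat)
        hist.to_csv(OUT / f"clone_histogram_{strand}.tsv", sep="\t", index=False)
        entry = {"mutated_clones": int(len(mat.clone_ids)),
                 "singly_mutated_fraction": clones.singly_mutated_fraction(mat)}
        try:
            entry["cluster_fraction_10nt"] = clones.cluster_fraction(mat, window=10)
        except ValueError:
            entry["cluster_fraction_10nt"] = None
        print(f"--- {strand}: {entry['mutated_clones']} mutated clones, "
              f"{100 * entry['singly_mutated_fraction']:.1f}% singly mutated ---")
        try:
            fit, cd = clones.correlation_length_from_matrix(mat)
            cd.to_csv(OUT / f"correlation_{strand}.tsv", sep="\t", index=False)
            entry["correlation_length_nt"] = fit.L
            entry["fit_residual"] = fit.residual
            print(f"  correlation length L = {fit.L:.1f} nt "
                  f"(weighted RMS residual {fit.residual:.2f}, {fit.n_points} distances)")
            # permutation null: shuffle each column independently
            rng = np.random.default_rng(RNG_SEED)
            multi = mat.restrict(2)
            shuffled = np.column_stack([rng.permutation(c) for c in multi.matrix.T])
            null_mat = clones.CloneMutationMatrix(strand=strand, coords=coords,
                                                  matrix=shuffled)
            c_null = clones.mutation_covariance(null_mat, scope="all")
            cd_null = clones.distance_correlation(c_null, coords)
            entry["null_mean_C"] = float(np.average(cd_null["C"],
                                                    weights=cd_null["n_pairs"]))
            print(f"  short-range C(d<=5) = {cd[cd['d'] <= 5]['C'].mean():.3f} vs "
                  f"permutation-null mean {entry['null_mean_C']:.3f}")
        except ValueError as exc:
            entry["correlation_length_nt"] = None
            print(f"  correlation fit unavailable: {exc}")
        report[strand] = entry
    with open(OUT / "clone_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"\nwrote clone statistics to {OUT}")


if __name__ == "__main__":
    main()
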