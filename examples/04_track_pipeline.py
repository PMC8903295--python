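"""From a population-averaged occupancy track to an error curve.

Builds a synthetic island-structured track (a stand-in for per-nucleosome
ChIP occupancy), binarizes it into single-cell-like mothers, replicates
and corrects them at a range of thresholds, and estimates the mark's
persistence parameters from the realizations.
"""

from epifill import estimate_from_track, make_two_level_track, normalize_track
from epifill.experiments import ExperimentConfig, run_track_pipeline

track = make_two_level_track(n=1000, island_len=10, gap_len=10, high=0.9, low=0.05)
params = estimate_from_track(normalize_track(track), n_realizations=50, seed=4)
print(f"estimated alpha = {params.alpha:.3f}, beta = {params.beta:.3f}")

cfg = ExperimentConfig(n_mothers=50, n_daughters=20, seed=5)
table, profiles = run_track_pipeline(cfg, track, range(0, 11))
print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
best = table.loc[table.mean_error.idxmin()]
print(f"\nbest threshold k_t = {int(best.k_t)}; corrected-daughter occupancy at"
      f" that k_t averages {profiles[int(best.k_t)].mean():.3f}"
      f" vs mother track mean {track.values.mean():.3f}")
# The interior minimum mirrors what per-nucleosome H3K27me3 data shows:
# a finite threshold (~5) reconstructs the population pattern best.
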