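"""From regular frames to sparse/dense superresolution localization images.

Runs the localization pipeline on a simulated series, superimposes all frames
into the dense image and a random 1/12 subset into the sparse image, and
compares both against each other with MS-SSIM — the core trade-off the
sparse-to-dense generator is trained to undo.
"""

import numpy as np

from palocal import localization, metrics, phantom

SEED = 0
config = phantom.ImagingConfig((64, 64), (25.0, 25.0), (125.0, 125.0),
                               noise_std=0.02)
tree = phantom.generate_vessel_tree(config.extent, 2, 3, SEED,
                                    root_radius=45.0, root_length=900.0)
series = phantom.render_series(tree, 60, 12, config, seed=SEED, mean_step=60.0)

event_sets = localization.localize_series(series, amplitude_threshold=0.25,
                                          dog_sigma=2.0)
n_events = sum(len(es) for es in event_sets)
print(f"localized {n_events} events across {len(series)} frames")

k = len(series) // 12
dense4 = localization.make_dense(event_sets, superres_factor=4, mode="sum")
print(f"dense superresolution image: {dense4.data.shape} from "
      f"{dense4.n_total} frames (4x finer grid than the regular frames)")

# the sparse/dense comparison on the grid the generator trains on
dense = localization.make_dense(event_sets, superres_factor=1, mode="sum")
sparse = localization.make_sparse(event_sets, k=k, seed=SEED,
                                  superres_factor=1, mode="sum", unit="frames")
speedup = localization.acquisition_speedup(sparse.n_total, sparse.k_used)
print(f"sparse uses {sparse.k_used}/{sparse.n_total} frames "
      f"-> {speedup:.0f}x faster acquisition")

score = metrics.ms_ssim(sparse.data, dense.data)
print(f"MS-SSIM(sparse, dense) = {score:.4f} "
      f"(the gap a generator is trained to close)")

# volumetric projections for the 3D regime
vol = np.random.default_rng(SEED).random((16, 16, 8))
mp = localization.map_project(vol)
depth, amp = localization.depth_encode(vol)
print(f"MAP of a {vol.shape} volume -> {mp.shape}; "
      f"depth map in [{depth.min()}, {depth.max()}]")
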