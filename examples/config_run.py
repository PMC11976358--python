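"""A full run driven by a TOML configuration file, with outputs on disk.

Writes the config, loads and validates it, simulates, computes metrics,
and exports snapshots (npz + per-time TSV), a metrics table, and a
manifest that records everything needed to reproduce the run.
"""

import tempfile
from pathlib import Path

import swarmlead as sl

CONFIG = """\
[model]
variant = "M3"

[params]
qa = 0.5
ql = 0.5
eta = 10.0
lambda1 = 0.2
lambda2 = 0.9

[grid]
n_cells = 400

[ic]
Mu = 12.61
Mv = 12.61
x0 = 5.0
seed = 3

[run]
t_end = 100.0
snapshot_every = 40
"""

workdir = Path(tempfile.mkdtemp(prefix="swarmlead_"))
cfg_path = workdir / "run.toml"
cfg_path.write_text(CONFIG)

bundle = sl.load_config(cfg_path)
result = sl.run_m2m3(bundle.params, bundle.follower_ic, bundle.leader_ic,
                     bundle.run, bundle.grid)
metrics = sl.compute_metrics(result)
manifest = sl.write_outputs(result, metrics, workdir / "out",
                            config=bundle.raw, seed=bundle.follower_ic.seed)

print(f"config:   {cfg_path}")
print(f"outputs:  {workdir / 'out'}")
print(f"regime:   {metrics.regime}")
print(f"speed:    {metrics.mean_speed:+.4f}   cohesion: {metrics.cohesion_index:.3f}")
print(f"manifest: seed={manifest.seed}, files={list(manifest.outputs)}")
print()
print("The manifest plus the seed make the run bit-for-bit reproducible.")
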