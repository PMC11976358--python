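"""Observant vs persuadable leaders under an orientation bias (Obias).

Both populations now react to each other; leaders sense a rightward
environmental cue of strength eta. At moderate alignment both leader types
shepherd the swarm coherently to the target; the persuadable type (M3) is
a little faster because followers reinforce the leaders' heading.
"""

import swarmlead as sl

grid = sl.Grid(800, 40.0)
followers = sl.InitialConditionSpec(M=12.61, x0=5.0, seed=21)
leaders = sl.InitialConditionSpec(M=12.61, x0=5.0, seed=22)
params = sl.ModelParams(lambda1=0.2, lambda2=0.9, gamma=0.1,
                        qa=0.5, ql=0.5, eta=10.0)

for model in ("M2", "M3"):
    run = sl.RunSpec(t_end=400.0, model=model, snapshot_every=40)
    result = sl.run_m2m3(params, followers, leaders, run, grid)
    m = sl.compute_metrics(result)
    label = "observant" if model == "M2" else "persuadable"
    print(f"{model} ({label} leaders):")
    print(f"  regime         {m.regime}")
    print(f"  mean speed     {m.mean_speed:+.4f}  (follower speed limit is 0.1)")
    print(f"  cohesion index {m.cohesion_index:.3f}")
    print(f"  success        {m.success}")
    print()

print("Moderate alignment plus an orientation bias gives compact, target-")
print("directed co-migration for both leader types; M3's social feedback")
print("yields the higher group speed at this alignment strength.")
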