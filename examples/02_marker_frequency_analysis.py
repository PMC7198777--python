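"""Marker frequency analysis under three replication modes.

Simulates exponential/stationary coverage (1-kb windows, 500 reads/window)
for a 3-Mbp chromosome replicated (a) from a single origin in a polyploid
population, (b) in multifork mode, and (c) asynchronously from multiple
origins, then detects the origin and classifies the mode from the
normalized depth-ratio profile.
"""

from repliskew import (ReplicationModel, detect_origin, mfa_ratio,
                       ori_ter_ratio, simulate_depth_profiles)

L = 3_000_000
models = {
    "single origin, r=0.3": ReplicationModel(
        "single_origin", L, ori_position=0, replicating_fraction=0.3, seed=1),
    "multifork, k=1.5": ReplicationModel(
        "multifork", L, ori_position=0, fork_intensity=1.5, seed=2),
    "asynchronous multi-origin": ReplicationModel(
        "multi_origin_async", L, seed=3),
}

for name, model in models.items():
    exp, stat = simulate_depth_profiles(model, window=1000, mean_depth=500.0)
    profile = mfa_ratio(exp, stat)  # 1-kb fine, 100-kb coarse windows
    call = detect_origin(profile, seed=model.seed)
    ratio = ori_ter_ratio(profile, 0)
    origin = "-" if call.origin_position is None else f"{call.origin_position:,}"
    print(f"{name:<28} mode={call.mode:<18} origin={origin:>9} "
          f"ori/ter={ratio:.2f} peak/trough={call.peak_trough_ratio:.2f}")

print("\nA single origin yields a V-shaped ratio peaking at ori (ori/ter = 1+r);")
print("multifork growth pushes ori/ter above 2 (= 2^k); asynchronous")
print("multi-origin replication leaves the profile flat (ratio ~ 1).")
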