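"""When is barcode-free duplicate grouping safe?

Treating reads with identical 5' coordinates as PCR copies of one molecule
breaks down when two *distinct* cfDNA fragments happen to share start and
end positions (a "collision").  This script evaluates the length-weighted
birthday model for a typical cfDNA library and scans depth.
"""

from pec.collision import collision_probability, depth_threshold_scan

MU, SIGMA = 177.0, 20.0  # fragment-length mean/SD (bp), typical cfDNA

p = collision_probability(D=300, mu=MU, sigma=SIGMA)
print(f"cfDNA depth 300x, fragment lengths N({MU:.0f}, {SIGMA:.0f}):")
print(f"  collision probability p = {p:.3f}")
print(f"  i.e. ~{100 * p:.1f}% of target loci are expected to hold reads from")
print("  two different molecules that coordinate-based grouping would merge.\n")

print("depth scan (p grows steeply with cfDNA depth):")
print("depth\tp_collision")
for D, p in depth_threshold_scan(MU, SIGMA, [100, 200, 300, 400, 500, 700]):
    print(f"{D:g}\t{p:.4f}")
print("\nBeyond ~500x cfDNA depth the collision rate becomes prohibitive and")
print("grouping should fall back to barcoded (UMI) protocols.")
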