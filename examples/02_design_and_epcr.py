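"""Design primers for mined loci and verify them by electronic PCR.

For each locus the designer searches the flanks for a primer pair with
melting temperature 58-62 degC, length 18-24 bp, GC 45-55 % and an
expected product of 100-250 bp containing the repeat.  Each designed
pair is then used to in-silico amplify its own genome: every pair must
recover its locus, and the product count gives the marker's copy number.
"""

from palmsat import (
    PlantedSSR,
    SyntheticGenomeSpec,
    amplify,
    classify_copy_number,
    design_all,
    find_ssrs,
    generate_genome,
)

spec = SyntheticGenomeSpec(
    length=20_000,
    planted_ssrs=tuple(PlantedSSR(u, c) for u, c in
                       [("at", 7), ("ga", 6), ("ctt", 5), ("tg", 8)]),
    seed=23,
)
genome, _ = generate_genome(spec)
loci = find_ssrs(genome)
pairs, failures = design_all(genome, loci)
print(f"{len(loci)} loci mined; {len(pairs)} primer pairs designed, "
      f"{len(failures)} undesignable")
for f in failures:
    print(f"  failed {f.locus.unit}x{f.locus.repeat_count} "
          f"at {f.locus.start}: {f.reason}")

print()
print("marker            product  Tm(f)  Tm(r)  copies")
for pair in pairs[:8]:
    products = amplify(genome, pair)
    cls = classify_copy_number(len(products)) or "0"
    print(f"{pair.marker_id:<16} {pair.expected_product_size:>7} "
          f"{pair.forward_tm:>6.1f} {pair.reverse_tm:>6.1f}  {cls:>5}")
print()
print("A copy number of 1 marks a locus unique in the genome - the kind")
print("of marker genotyping studies prefer.")
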