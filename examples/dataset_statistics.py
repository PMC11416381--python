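"""Dataset-level statistics of a peptide screening library.

Generates a study-sized synthetic dataset (158 peptides, 10-13 residues,
K/R/S/T-enriched composition, planted motif effects) and prints the
pairwise-identity histogram and residue frequencies — the two checks used
to confirm that a screening dataset is heterogeneous rather than a family
of near-duplicates.
"""

from regexgp import aa_frequencies, generate_dataset, identity_distribution

ds = generate_dataset(158, rng=1)
print(f"{len(ds)} peptides, lengths {min(map(len, ds))}-{max(map(len, ds))}")

dist = identity_distribution(ds, cutoff=50.0)
print(f"\npairwise identity over {dist['n_pairs']} pairs:")
for lo, hi, f in zip(dist["bin_edges"][:-1], dist["bin_edges"][1:], dist["fractions"]):
    print(f"  [{lo:3.0f},{hi:3.0f}) {'#' * int(60 * f)} {100 * f:.1f}%")
print(f"pairs above 50% identity: {100 * dist['fraction_above_cutoff']:.2f}%")
# a heterogeneous library has most pairs in the lowest bins — high-identity
# pairs would mean the dataset over-represents a few sequence families

freqs = aa_frequencies(ds)
top = sorted(freqs, key=freqs.get, reverse=True)[:5]
print("\nmost frequent residues:", ", ".join(f"{aa} {100 * freqs[aa]:.1f}%" for aa in top))
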