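"""Order sorted cell populations into a lineage hierarchy by shared variants.

Three FACS-sorted populations (pre-leukemic HSCs, leukemic stem cells,
blasts) are called independently; variants present in several populations
were inherited from a shared ancestor, while population-specific ones mark
later subclonal expansion.  Here the tables are built directly to mirror a
typical patient: two founder heteroplasmies in all three populations, one
acquired in the LSC and passed to blasts, and one private to the pHSCs.
"""

from mitolineage import VariantCall, population_hierarchy


def call(pos, ref, alt, vaf, depth=1500):
    n = max(int(vaf * depth), 2)
    return VariantCall(pos, ref, alt, vaf, depth, n // 2, n - n // 2)


tables = {
    "pHSC": [call(6776, "T", "C", 0.21), call(3010, "G", "A", 0.09),
             call(2967, "G", "A", 0.04)],
    "LSC": [call(6776, "T", "C", 0.24), call(3010, "G", "A", 0.11),
            call(5178, "C", "A", 0.06)],
    "blast": [call(6776, "T", "C", 0.23), call(3010, "G", "A", 0.10),
              call(5178, "C", "A", 0.07)],
}

table = population_hierarchy(tables, report_cut=0.01).table
print(table.to_string(index=False))
print("\nVariants shared by all populations sit at the apex of the lineage; "
      "the LSC+blast variant marks the leukemic branch; the pHSC-private "
      "variant marks a clone that did not transform.")
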