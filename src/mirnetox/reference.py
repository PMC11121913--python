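"""Small bundled reference data used by fixtures and worked examples.

``PSYCHIATRIC_MIRNA_ALIASES`` is a compact demonstration catalogue of
miRNAs repeatedly reported as dysregulated in psychiatric disorders
(largely schizophrenia), each as a (canonical mature name, older alias)
pair — the alias being the pre-arm-annotation name in use before miRBase
v17.  It backs the alias-conversion and disease-set fixtures; it is not
a curated resource for production use.
"""

PSYCHIATRIC_MIRNA_ALIASES: list[tuple[str, str]] = [
    ("hsa-miR-17-5p", "hsa-miR-17"),
    ("hsa-miR-432-5p", "hsa-miR-432"),
    ("hsa-miR-106b-5p", "hsa-miR-106b"),
    ("hsa-miR-30b-5p", "hsa-miR-30b"),
    ("hsa-miR-29c-3p", "hsa-miR-29c"),
    ("hsa-miR-328-3p", "hsa-miR-328"),
    ("hsa-miR-652-3p", "hsa-miR-652"),
    ("hsa-miR-33a-5p", "hsa-miR-33"),
    ("hsa-miR-195-5p", "hsa-miR-195"),
    ("hsa-miR-181b-5p", "hsa-miR-181b"),
    ("hsa-miR-107", "hsa-miR-107"),
    ("hsa-miR-193b-3p", "hsa-miR-193b"),
    ("hsa-miR-134-5p", "hsa-miR-134"),
    ("hsa-miR-409-3p", "hsa-miR-409-3p"),
    ("hsa-miR-346", "hsa-miR-346"),
]

# Demonstration panel of oxidative-stress-responsive mature miRNAs from the
# imprinted DLK1-DIO3 locus (14q32), per treatment regimen, with a flag for
# whether any prior schizophrenia/immune expression study reported the same
# precursor as dysregulated.  Backs the cluster-annotation worked example.
DLK1_DIO3_PANEL: list[tuple[str, str, bool]] = [
    ("hsa-miR-432-5p", "co", True),
    ("hsa-miR-370-3p", "co", True),
    ("hsa-miR-485-3p", "co", True),
    ("hsa-miR-495-3p", "co", True),
    ("hsa-miR-376b-3p", "co", True),
    ("hsa-miR-889-3p", "co", True),
    ("hsa-miR-758-3p", "co", True),
    ("hsa-miR-655-3p", "co", False),
    ("hsa-miR-496", "co", False),
    ("hsa-miR-369-3p", "co", False),
    ("hsa-miR-432-5p", "pre", True),
    ("hsa-miR-323a-3p", "pre", True),
    ("hsa-miR-134-5p", "pre", True),
    ("hsa-miR-485-5p", "pre", True),
]
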