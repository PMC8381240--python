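"""Parse the packaged GRCm38 ERV/LINE-1 locus catalog and export BED.

Loads the locus table shipped with the package, looks a locus up by alias,
computes its counting footprint, and prints the first BED lines.
"""

from retroloci import catalog as cat

loci = cat.load_table1_catalog()
print(f"{len(loci)} loci "
      f"({sum(l.element_class == 'ERV' for l in loci)} ERV, "
      f"{sum(l.element_class == 'LINE1' for l in loci)} LINE-1)")

# lookup works by primary name or alias (Xmv45 is the MLV-group flagship)
locus = cat.lookup(loci, "Xmv45")
fp = cat.locus_footprint(locus)
print(f"{locus.name}: {len(locus.segments)} gene segments on {fp.chrom} ({fp.strand})")
print(f"  counting footprint {fp.chrom}:{fp.start}-{fp.end} ({fp.length} bp)")

issues = cat.validate_catalog(loci)
print(f"validation: {sum(i.severity == 'error' for i in issues)} errors, "
      f"{sum(i.severity == 'warning' for i in issues)} warnings "
      f"(partial loci such as pol-only rows are warnings)")

bed = cat.export_bed(loci)
print("first BED lines (0-based half-open):")
for line in bed.splitlines()[:3]:
    print(" ", line)
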