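#!/usr/bin/env bash
# Optional helper: download the 1000 Genomes phase 3 slice covering the
# FTO intron 1 SNP cluster (hg19 chr16:53,760,000-53,850,000) plus the
# integrated sample panel, for running the pipeline on real data.
#
# Requires network access, bcftools and tabix. Never invoked by the tests.
#
# Usage: scripts/fetch_1000g.sh <output-dir>

set -euo pipefail

OUT=${1:?usage: fetch_1000g.sh <output-dir>}
mkdir -p "$OUT"

BASE=http://ftp.1000genomes.ebi.ac.uk/vol1/ftp/release/20130502
VCF=$BASE/ALL.chr16.phase3_shapeit2_mvncall_integrated_v5b.20130502.genotypes.vcf.gz
PANEL=$BASE/integrated_call_samples_v3.20130502.ALL.panel

# region slice only (the full chr16 file is ~1.8 GB)
bcftools view -r 16:53760000-53850000 "$VCF" -Oz -o "$OUT/fto_region.vcf.gz"
bcftools index -t "$OUT/fto_region.vcf.gz"

curl -fsSL "$PANEL" -o "$OUT/samples_all.panel"

# keep the four continental supergroups analysed here (AMR excluded) and
# rename the header to the column names haplopop expects
awk 'BEGIN{FS=OFS="\t"} NR==1{print "sample","pop","super_pop","sex"; next}
     $3=="AFR"||$3=="EAS"||$3=="EUR"||$3=="SAS"{print $1,$2,$3,$4}' \
    "$OUT/samples_all.panel" > "$OUT/samples.tsv"

echo "wrote $OUT/fto_region.vcf.gz and $OUT/samples.tsv"
echo "run: haplopop run-all --vcf $OUT/fto_region.vcf.gz \\"
echo "       --snp-panel <panel.tsv> --sample-panel $OUT/samples.tsv \\"
echo "       --out-dir $OUT/bundle --seed 1"
echo "(write the SNP panel with haplopop.panel.write_snp_panel(haplopop.fto.fto_panel(), 'panel.tsv'))"
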