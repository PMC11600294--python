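# Known bioinformatics tool names used for software recognition in plan
# parsing (one per line; matching is case-insensitive on word boundaries).
FastQC
Trimmomatic
Trim Galore
Cutadapt
SPAdes
QUAST
BWA
Bowtie
Bowtie 2
Bowtie2
HISAT2
STAR
Minimap2
Samtools
BCFtools
GATK
ensembl-vep
manta
pindel
SnpEff
MACS2
MACS
BEDTools
IGV
HOMER
MEME
DESeq2
edgeR
limma
g:Profiler
gprofileR
Bismark
GREAT
canu
Racon
Flye
Medaka
Bandage
trf
FALCON
Quiver
MUMmer
HTSeq
htseq-count
featureCounts
subread
StringTie
cufflinks
gffcompare
fusioncatcher
rMATs
DaPars
ballgown
CIRI2
CIRIQuant
miRDeep2
CAGEr
Piranha
RiboTaper
Cell Ranger
CellRanger
Seurat
Scanpy
Squidpy
AnnData
Tangram
proteowizard
OpenMS
pymzml
salmon
kallisto
picard
deeptools
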