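# Forty-case evaluation registry: expert-judged stage outcomes (plan
# proposal / code generation / code execution) for the agent run without
# automatic code repair, per case, plus the with-repair variant.
# With-repair per-case outcomes were published only as aggregates; cells
# that cannot be attributed to a specific case are marked "unknown" and the
# summarizer resolves them against data/acr_aggregates.json. All
# execute-stage failures of the no-repair variant are "pass" with repair:
# the with-repair codegen and execute aggregate counts are equal, so every
# case that generated code also executed. Stage values: pass|fail|unknown.
case_id,pipeline_class,task,omics,plan_noacr,codegen_noacr,execute_noacr,plan_acr,codegen_acr,execute_acr,failure_reason,tools,time_min
1.1,WGS data analysis,Genome assembly,genomics,pass,pass,pass,pass,pass,pass,,FastQC;Trimmomatic;SPAdes;QUAST,3
2.1,WGS/WES data analysis,Somatic SNV+indel calling,genomics,pass,pass,pass,pass,pass,pass,,FastQC;Trimmomatic;BWA;Samtools;GATK,8
2.2,WGS/WES data analysis,Somatic SNV+indel calling and annotation,genomics,pass,pass,pass,pass,pass,pass,,FastQC;Trimmomatic;BWA;Samtools;GATK;ensembl-vep,8
2.3,WGS/WES data analysis,Structure variation identification with normal,genomics,pass,pass,pass,pass,pass,pass,,FastQC;Trimmomatic;BWA;Samtools;GATK;manta,18
2.4,WGS/WES data analysis,Structure variation identification without normal,genomics,pass,pass,fail,pass,pass,pass,Failed: pindel requires configuration file,FastQC;Trimmomatic;BWA;Samtools;pindel;SnpEff,6
3.1,ChIP-seq data analysis,Peak calling,genomics,pass,pass,pass,pass,pass,pass,,FastQC;Trim Galore;Bowtie 2;Samtools;MACS2;BEDTools;IGV,6
3.2,ChIP-seq data analysis,Motif discovery for binding sites,genomics,pass,pass,pass,pass,pass,pass,,FastQC;Trim Galore;Bowtie2;MACS2;HOMER;MEME,4
3.3,ChIP-seq data analysis,Functional enrichment of target gene,genomics,fail,fail,fail,fail,fail,fail,Failed: DESeq2 is not suitable for peaks identified by MACS2,FastQC;BWA;MACS;BEDTools;DESeq2;g:Profiler;R,6
4.1,Bisulfite-Seq data analysis,Identifying DNA methylation,genomics,pass,pass,pass,pass,pass,pass,,Trim Galore;Bismark;IGV,9
5.1,ATAC-seq data analysis,Identifying open chromatin regions,genomics,pass,pass,fail,pass,pass,pass,Failed: wrongly used BEDTools,Trim Galore;BWA;Samtools;MACS2;BEDTools,8
6.1,DNase-seq data analysis,Identifying DNaseI hypersensitive site,genomics,pass,pass,pass,pass,pass,pass,,FastQC;Cutadapt;BWA;MACS2;IGV;GREAT,5
7.1,4C-seq data analysis,Find genomics interactions,genomics,pass,pass,pass,pass,pass,pass,,FastQC;BEDTools;Samtools;Bowtie 2;R,6
8.1,Nanopore DNA sequencing data analysis,Genome assembly,genomics,pass,pass,fail,pass,pass,pass,Failed: racon medaka wrongly used the parameters,canu;Minimap2;Racon;Flye;Medaka;Bandage,7
8.2,Nanopore DNA sequencing data analysis,Tandem repeats variation identification,genomics,fail,fail,fail,fail,fail,fail,Failed: cannot find a correct pipeline,Minimap2;Samtools;trf,7
9.1,PacBio DNA sequencing data analysis,Genome assembly,genomics,pass,fail,fail,pass,unknown,unknown,"Failed: install the wrong tool, pb-falcon rather than falcon",Canu;FALCON;Quiver;MUMmer,7
10.1,RNA-Seq data analysis,Find Differentially expressed genes,transcriptomics,pass,pass,pass,pass,pass,pass,,FASTQC;Trimmomatic;HISAT2;htseq;DESeq2,5
10.2,RNA-Seq data analysis,Identify the top5 downregulated genes,transcriptomics,pass,pass,pass,pass,pass,pass,,FASTQC;Trimmomatic;HISAT2;htseq;DESeq2;gprofileR,5
10.3,RNA-Seq data analysis,Predict Fusion gene with annotation,transcriptomics,pass,pass,pass,pass,pass,pass,,gunzip;HISAT2;fusioncatcher;gffcompare,6
10.4,RNA-Seq data analysis,Isoform expression,transcriptomics,pass,pass,pass,pass,pass,pass,,Trim Galore;HISAT2;Samtools;StringTie,5
10.5,RNA-Seq data analysis,Splicing analysis,transcriptomics,pass,pass,pass,pass,pass,pass,,Trimmomatic;HISAT2;Samtools;StringTie;featureCounts;rMATs,6
10.6,RNA-Seq data analysis,APA analysis,transcriptomics,pass,fail,fail,pass,unknown,unknown,Failed: DaPars (not available in conda),Trim Galore;HISAT2;StringTie;DaPars,7
10.7,RNA-Seq data analysis,RNA editing,transcriptomics,fail,fail,fail,fail,fail,fail,Failed: cannot find a correct pipeline,FastQC;Trimmomatic;HISAT2;Samtools;StringTie;ballgowan;GATK,7
10.8,RNA-Seq data analysis,Circular RNA identification,transcriptomics,pass,fail,fail,pass,unknown,unknown,Failed: CIRI2 (not available in conda),Trim Galore;HISAT2;CIRI2;CIRIQuant,5
11.1,Small RNA sequencing data analysis,microRNA quantification,transcriptomics,pass,pass,pass,pass,pass,pass,,Fastqc;Cutadapt;Bowtie;Samtools;subread/featureCounts;DESeq2;edgeR,11
11.2,Small RNA sequencing data analysis,microRNA prediction,transcriptomics,pass,pass,fail,pass,pass,pass,Failed: conda of miRDeep2 is problematic,Fastqc;Cutadapt;Bowtie;Samtools;featureCounts;miRDeep2;DESeq2;edgeR,11
12.1,CAGE-seq data analysis,TSS identification,transcriptomics,pass,pass,pass,pass,pass,pass,,Fastqc;Trimmomatic;HISAT2;HTSeq/htseq-count;CAGEr,6
13.1,3' end-seq data analysis,PAS (polyadenylation site) identification,transcriptomics,fail,fail,fail,fail,fail,fail,Failed: cannot find a correct pipeline,Trim Galore;HISAT2;StringTie;DaPars,5
14.1,Nanopore RNA sequencing data analysis,Isoform expression,transcriptomics,pass,pass,fail,pass,pass,pass,Failed: prepDE.py no need to run with 'python prepDE.py',Minimap2;Samtools;StringTie;DESeq2,9
15.1,PacBio RNA sequencing data analysis,Isoform expression,transcriptomics,pass,pass,pass,pass,pass,pass,,Minimap2;Samtools;StringTie;cufflinks,5
16.1,CLIP-seq data analysis,Identify protein-RNA crosslink sites,transcriptomics,pass,pass,fail,pass,pass,pass,Failed: conda of Piranha is problematic,FastQC;Cutadapt;Bowtie2;Samtools;BEDTools;Piranha,6
16.2,RIP-seq data analysis,Find enriched genes bounded by RBP,transcriptomics,pass,pass,pass,pass,pass,pass,,FastQC;Trim Galore;HISAT2;htseq;DESeq2,4
17.1,Ribo-seq data analysis,Identify translated ORFs,transcriptomics,pass,pass,fail,pass,pass,pass,Failed: not regular conda of ribotaper,FastQC;Trim Galore;HISAT2;Samtools;StringTie;RiboTaper,7
18.1,single-cell RNA-seq data analysis,Cell clustering from fastq data,transcriptomics,pass,pass,pass,pass,pass,pass,,Cell Ranger;Seurat,5
18.2,single-cell RNA-seq data analysis,Find differentially expressed genes based on count matrix,transcriptomics,pass,pass,pass,pass,pass,pass,,Scanpy,8
18.3,single-cell RNA-seq data analysis,Find marker genes based on count matrix,transcriptomics,pass,pass,pass,pass,pass,pass,,Scanpy,6
18.4,single-cell RNA-seq data analysis,Cell clustering and visualization,transcriptomics,pass,pass,pass,pass,pass,pass,,Scanpy,5
19.1,Spatial transcriptomics,Neighborhood enrichment analysis,transcriptomics,pass,pass,pass,pass,pass,pass,,Squidpy;AnnData,5
19.2,Spatial transcriptomics,Single-cell mapping,transcriptomics,pass,pass,pass,pass,pass,pass,,AnnData;Scanpy;Tangram,3
20.1,Mass spectrometry data analysis,Protein expression quantification,proteomics,pass,pass,pass,pass,pass,pass,,proteowizard;OpenMS,15
21.1,Mass spectrometry data analysis,Metabolites quantification,metabolomics,pass,pass,pass,pass,pass,pass,,pymzml;pandas;numpy;scipy,13
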