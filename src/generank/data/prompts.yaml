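# Scoring rubric and step-prompt templates for the candidate-gene
# prioritization workflow.  Templates use named-brace placeholders; the
# required_keys manifest is authoritative (rendering fails fast on a
# missing key).  List-valued context entries are joined by single spaces.
rubric:
  score_min: 0
  score_max: 10
  comment_threshold: 4
  statements:
    - key: a
      theme: biological significance
      text: The gene is associated with erythroid cells or erythropoiesis.
    - key: b
      theme: biomarker relevance
      text: The gene is currently being used as a biomarker in clinical settings.
    - key: c
      theme: biomarker relevance
      text: The gene has potential value as a blood transcriptional biomarker.
    - key: d
      theme: biological significance
      text: The gene is relevant to circulating leukocytes immune biology.
    - key: e
      theme: therapeutic relevance
      text: The gene is a known drug target.
    - key: f
      theme: therapeutic relevance
      text: The gene is therapeutically relevant for immune-mediated diseases.
  guide:
    "0": "No evidence found."
    "1–3": "Very limited evidence."
    "4–6": "Some evidence, but needs validation or is limited to certain conditions."
    "7–8": "Good evidence, used or proposed for some clinical applications."
    "9–10": "Strong evidence, firmly established as a useful biomarker."
templates:
  "2.1":
    required_keys: [genes]
    template: "Could you identify functional convergences among this set of genes? {genes}"
  "2.2":
    required_keys: []
    template: "Could you generate a R script to visualize these relationships as a network, with nodes representing themes and genes, and edges representing functional associations between genes and themes and among genes?"
  "3.1":
    required_keys: [statement_a, statement_b, statement_c, statement_d, statement_e, statement_f]
    template: |-
      I am next going to ask for a given gene to:
      Provide the gene's official name.
      Provide a brief summary of the gene's function.
      Give each of the following statements a score from 0 to 10, with 0 indicating no evidence and 10 indicating very strong evidence:
      a. {statement_a}
      b. {statement_b}
      c. {statement_c}
      d. {statement_d}
      e. {statement_e}
      f. {statement_f}

      Scoring criteria:
      0—No evidence found.
      1–3—Very limited evidence.
      4–6—Some evidence, but needs validation or is limited to certain conditions.
      7–8—Good evidence, used or proposed for some clinical applications.
      9–10—Strong evidence, firmly established as a useful biomarker.

      For scores of 4 or above please provide an evaluative comment and up to three key supporting references using as a format: First author, Title, Date, Journal.

      The results should be generated in the following format, using | as a delimiter and on a single line:

      Gene symbol | Gene name | a brief summary | evaluative comment for statement a | supporting references for statement a | score for statement a | and so on for statements b, c, d, e and f.
  "3.2":
    required_keys: [example_gene, example_record]
    template: "Just to give an idea of what the output should look like, here is an example for the gene {example_gene}: {example_record}"
  "3.3":
    required_keys: [gene]
    template: "Now go ahead with the evaluation of this gene: {gene}"
  "4.1":
    required_keys: [justifications]
    template: |-
      Could you generate a coherent summary paragraph based on the information provided below? The style needs to be technical, direct and to the point.
      {justifications}
  "5.1":
    required_keys: [statement]
    template: |-
      Could you fact-check and provide a couple of supporting references for this statement?
      {statement}
  "6.1":
    required_keys: [summary]
    template: |-
      Based on the summary provided below, could you select a top candidate based on: relevance to (1) erythroid cells or erythropoiesis, (2) current use as a biomarker, (3) potential use as a blood transcriptional biomarker, (4) relevance to leukocytes immune biology, (5) being a known drug target, and (6) being of therapeutic relevance for immune mediated diseases? Equal weight should be given to each of those 6 criteria:
      {summary}
  "6.2":
    required_keys: [genes]
    template: |-
      For the list of genes provided below, could you select a top candidate based on: relevance to (1) erythroid cells or erythropoiesis, (2) current use as a biomarker, (3) potential use as a blood transcriptional biomarker, (4) relevance to leukocytes immune biology, (5) being a known drug target, and (6) being of therapeutic relevance for immune mediated diseases? Equal weight should be given to each of those 6 criteria. {genes}
  "7.1":
    required_keys: [summary]
    template: |-
      Based on the summary below, please recommend the top candidate gene to include in a targeted blood transcriptional profiling panel. The intent is for the selected gene to be representative of an erythroid cell signature associated with response to mRNA vaccines, severity of RSV infection and that found to be expressed at high levels in patients with metastatic melanoma and in liver transplant recipients. Please weigh the following criteria equally in your recommendation: (1) Relevance to erythroid cells and erythropoiesis, (2) Current use as a biomarker, (3) Potential use as a blood transcriptional biomarker, (4) Relevance to leukocyte immune biology, (5) Status as a known drug target, (6) Therapeutic relevance for immune mediated diseases:
      {summary}
  "7.2":
    required_keys: [data]
    template: |-
      Now that you have provided an initial recommendation based on the summary, take into account the following RNA-sequencing expression data from key immune cell types and whole blood samples:
      {data}

      Given this additional RNA-seq expression data, does your recommended gene selection remain the same? Please explain which gene you would recommend at this stage and why, incorporating both the summarized information provided earlier and RNA-seq data in your rationale.
  "7.3":
    required_keys: [data]
    template: |-
      Now that you have provided an initial recommendation based on the summary and the RNAseq data, take into account the following microarray expression data from key immune cell types and hematopoietic precursors:
      {data}

      Given this additional microarray expression data, does your recommended gene selection remain the same? Please explain which gene you would recommend at this stage and why, incorporating the summarized information and RNA-seq data provided earlier, as well as this new microarray data in your rationale.
  "7.4":
    required_keys: [data]
    template: |-
      Now that you have provided an initial recommendation based on the summary and the immune cells RNAseq and microarray data, take into account the following averaged log2 fold changes in RNA abundance in patient cohorts compared to controls.
      {data}

      Given this additional data, does your recommended gene selection remain the same? Please explain which gene you would recommend at this stage and why, incorporating the summarized information, the leukocytes RNA-seq and microarray data provided earlier, as well as these new patient cohort profiles in your rationale.
  "7.5":
    required_keys: []
    template: "Could you summarize the key conclusions you have drawn from the conversation so far?"
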