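# Synthetic offline citation-resolution table for the fact-check stub.
# Keys: first_author, year, title (lexically normalized).  The PMID column
# holds placeholder identifiers for offline testing; it is NOT a PubMed
# mirror.  Entries cover the worked-example citations plus citations used
# by the simulated backends.
first_author	year	title	journal	pmid
Wang	2020	Glutathione peroxidase 4 and vitamin E cooperatively prevent hepatocellular degeneration	Redox Biology	900000001
Banning	2018	Glutathione Peroxidase 4: A new player in neurodegeneration?	Molecular Neurobiology	900000002
Iuchi	2017	Glutathione Peroxidase 4 Overexpression Inhibits ROS-Induced Cell Death in Diffuse Large B-cell Lymphoma	Lab Invest	900000003
Yang	2014	Regulation of ferroptotic cancer cell death by GPX4	Cell	900000004
Friedmann Angeli	2014	Inactivation of the ferroptosis regulator Gpx4 triggers acute renal failure in mice	Nature Cell Biology	900000005
Ducamp	2019	The molecular genetics of sideroblastic anemia	Blood	900000006
Perrotta	2008	Hereditary spherocytosis	Lancet	900000007
Sachar	2016	Protoporphyrin IX: the Good, the Bad, and the Ugly	J Pharmacol Exp Ther	900000008
Supuran	2008	Carbonic anhydrases: novel therapeutic applications for inhibitors and activators	Nat Rev Drug Discov	900000009
Croker	2011	Fas-mediated neutrophil apoptosis is accelerated by Bid, Bak, and Bax and inhibited by Bcl-2 and Mcl-1	Proc Natl Acad Sci	900000010
Doe	2021	A synthetic study of SYN1 and criterion a	Journal of Simulated Biology	900000011
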