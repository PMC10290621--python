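gene_id	ecg_phenotype	behavior_phenotype	npd_annotation
Psmc6	HR ↑ HRV ↓	Hyperactivity, decreased thigmotaxis	Limited or no NPD annotations
1700086L19Rik	rMSSD, HRV ↓	Hyperactivity	Limited or no NPD annotations
Mpst	PQ ↓, HR ↑, PR ↓	Decreased exploration of a novel environment, increased latency to center entry, hypoactivity	Limited or no NPD annotations
Mdp1	HR ↑	Increased latency to the first transition into the dark in light/dark box, decreased % prepulse inhibition	Bipolar disorder, mood disorder
Gsg1l	HR ↓ (F), HR ↑ (M), RR ↑ (F), RR ↓ (M)	Hyperactivity, decreased startle response	Limited or no NPD annotations
Cdc26	HR ↑	Increased prepulse inhibition	Limited or no NPD annotations
Chmp2b	HR, RR ↑	Abnormal freezing behavior in fear conditioning	Tourette's syndrome or obsessive-compulsive disorder, frontotemporal dementia
Pitx3	HR ↑, ST, RR, QTc ↓	Hyperactivity, increased coping response, decreased vertical activity, decreased exploration of a novel environment	Cognitive ability, Parkinson's disease
Prokr1	HR ↑, RR ↓, rMSSD ↑	No	Limited or no NPD annotations
Arid4b	HR, QRS ↑	Decreased centre time	Limited or no NPD annotations
Zfp395	HR ↑ ST, RR ↓	Hyperactivity	Limited or no NPD annotations
Stx1a	PQ ↑, HR ↓, ST, rMSSD, RR ↑ HR_TTE ↓	No	Disease of mental health
Hipk3	HR ↓, RR, HRV ↑	Decreased startle, hypoactivity, decreased prepulse inhibition, increased acoustic brainstem response thresholds	Limited or no NPD annotations
Srsf11	HRV ↑	Decreased prepulse inhibition	Limited or no NPD annotations
Tnnc1	HRV ↑	No	Feeling worry, Bipolar disorder, Autism spectrum disorder or schizophrenia
Kbtbd7	HR ↓, RR ↑	Hyperactivity, decreased thigmotaxis	Limited or no NPD annotations
Rasgef1a	HR ↓, RR ↑	Increased vertical activity	Recurrent major depressive disorder
Cap2	HR ↓, ST, rMSSD, RR, QTc ↑	No	Limited or no NPD annotations
Bclaf1	rMSSD ↑	Hyperactivity	Limited or no NPD annotations
Entpd1	rMSSD ↑	No	Limited or no NPD annotations
4931406C07Rik	HR ↓ rMSSD, HRV ↑	No	Limited or no NPD annotations
Fbxl16	ST, RR, QTc, HR ↑ HR_TTE ↓, HRV ↑	Unresponsive to tactile stimuli	Attention deficit hyperactivity disorder
Atn1	rMSSD, HRV ↑	Limb grasping, decreased exploration of novelty	Limited or no NPD annotations
Lpin3	HR ↓, RR ↑	No	Limited or no NPD annotations
Dnase1l2	HR ↓, RR ↑, LVIDd, LVIDs ↓	Abnormal vocalisation, decreased grip strength, abnormal motor capabilities/coordination/movement, hypoactivity, small superior vagus ganglion	Limited or no NPD annotations
Spred3	HRV ↑	Increased freezing behavior, decreased prepulse inhibition	Limited or no NPD annotations
Grm7	HR ↓, RR ↑	Hyperactivity, increased grip, decreased anxiety-related behavior, limb grasping	Recurrent major depressive disorder, Clozapine-induced agranulocytosis/granulocytopenia in treatment-resistant schizophrenia, Personality traits in bipolar disorder, Major depressive disorder (broad), Panic disorder, Neurodevelopmental disorder with seizures, hypotonia, and brain abnormalities
Cyp27a1	HR, QRS ↓, RR ↑	No	Limited or no NPD annotations
Agpat1	HR ↓, rMSSD, RR, HRV ↑	No	Clozapine-induced agranulocytosis/granulocytopenia in treatment-resistant schizophrenia, Autism spectrum disorder or schizophrenia
Ctsd	ST, RR ↑	No	Neuronal ceroid lipofuscinosis
P3h1	HR ↓, RR ↑	Decreased grip strength	Limited or no NPD annotations
Pnmt	QTc Dispersion, rMSSD ↑	Increased startle response, decreased exploration of novel environment, decreased breath rate during sleep	Limited or no NPD annotations
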