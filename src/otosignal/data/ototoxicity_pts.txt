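# MedDRA Preferred Terms defining drug-induced ototoxicity (cochlear and
# vestibular). One term per line; matching is case-insensitive.
acute vestibular syndrome
auditory disorder
deafness
deafness bilateral
deafness neurosensory
deafness unilateral
ear disorder
hyperacusis
hypoacusis
inner ear disorder
inner ear inflammation
meniere's disease
motion sickness
neurosensory hypoacusis
ototoxicity
presbyacusis
sudden hearing loss
tinnitus
vertigo
vertigo positional
vestibular disorder
vestibular neuronitis
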