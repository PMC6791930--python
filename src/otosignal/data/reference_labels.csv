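substance,event_group,expected
doxazosin,tinnitus,yes
bisoprolol,tinnitus,yes
nebivolol,tinnitus,no
ramipril,tinnitus,yes
irbesartan,tinnitus,yes
betamethasone,tinnitus,no
clarithromycin,hypoacusis,yes
azithromycin,hypoacusis,yes
amikacin,hypoacusis,yes
amikacin,tinnitus,yes
moxifloxacin,tinnitus,yes
vancomycin,hypoacusis,yes
ethambutol,tinnitus,no
efavirenz,tinnitus,yes
sofosbuvir and ledipasvir,tinnitus,no
methotrexate,hypoacusis,no
pemetrexed,hypoacusis,no
vincristine,hypoacusis,yes
vinorelbine,hypoacusis,no
etoposide,tinnitus,no
paclitaxel,hypoacusis,yes
cisplatin,hypoacusis,yes
cisplatin,tinnitus,yes
rituximab,hypoacusis,yes
interferon alfa-2b,hypoacusis,yes
abatacept,tinnitus,no
thalidomide,hypoacusis,yes
indometacin,tinnitus,yes
etoricoxib,tinnitus,yes
tapentadol,tinnitus,no
paroxetine,tinnitus,yes
sertraline,tinnitus,yes
"timolol, combinations",tinnitus,yes
deferasirox,hypoacusis,yes
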