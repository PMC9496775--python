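# Expansion list: high-frequency domain-neutral words removed on top of the
# default list when analysing COVID-19 narrative-medicine corpora.  The
# expanded list used on the original scraped corpus is unpublished; this one
# is a curated substitute and is configurable.
cosa
cose
detto
dire
essere
fatto
giorni
giorno
grande
mesi
mese
modo
molto
parte
persona
persone
prima
primo
proprio
punto
qualche
stata
state
vita
volta
volte
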