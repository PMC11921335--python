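voc,iur,rfc,provenance
benzene,7.8e-6,30,IRIS
acetaldehyde,2.2e-6,9,IRIS
"1,3-butadiene",3.0e-5,2,IRIS
carbon tetrachloride,6.0e-6,100,IRIS
chloroform,2.3e-5,,IRIS
ethylbenzene,2.5e-6,1000,IUR: OEHHA; RfC: IRIS
toluene,,5000,IRIS
xylene,,100,IRIS
"1,2,4-trimethylbenzene",,60,IRIS
"1,2,3-trimethylbenzene",,60,"IRIS (read-across from 1,2,4-TMB)"
methanol,,20000,IRIS
isopropanol,,7000,OEHHA chronic REL
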