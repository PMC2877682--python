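group,name,count
South Asian,Patel,35984
South Asian,Singh,31820
South Asian,Sharma,10216
South Asian,Kaur,7462
South Asian,Persaud,6982
South Asian,Sandhu,6229
South Asian,Grewal,6044
South Asian,Sidhu,5862
South Asian,Dhaliwal,5209
South Asian,Dhillon,4847
Chinese,Wong,34567
Chinese,Chan,32692
Chinese,Li,27608
Chinese,Chen,25618
Chinese,Wang,22548
Chinese,Liu,18784
Chinese,Zhang,18003
Chinese,Lam,15910
Chinese,Leung,13696
Chinese,Ho,12830
General Population,Smith,91575
General Population,Brown,57222
General Population,Lee,49898
General Population,Wilson,43803
General Population,Martin,38878
General Population,Taylor,35746
General Population,Campbell,34551
General Population,Williams,34104
General Population,Thompson,33810
General Population,Jones,32644
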