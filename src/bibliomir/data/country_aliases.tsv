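# alias	canonical (editable; lookup is case-insensitive on the alias column)
China	China
PR China	China
P.R. China	China
People's Republic of China	China
Hong Kong	China
Iran	Iran
Islamic Republic of Iran	Iran
Japan	Japan
Italy	Italy
United States	United States
United States of America	United States
USA	United States
U.S.A.	United States
US	United States
Germany	Germany
United Kingdom	United Kingdom
UK	United Kingdom
U.K.	United Kingdom
England	United Kingdom
Scotland	United Kingdom
Wales	United Kingdom
Great Britain	United Kingdom
India	India
Australia	Australia
France	France
Canada	Canada
South Korea	South Korea
Republic of Korea	South Korea
Korea	South Korea
Spain	Spain
Sweden	Sweden
Malaysia	Malaysia
Guatemala	Guatemala
New Zealand	New Zealand
Ireland	Ireland
Czech Republic	Czech Republic
Czechia	Czech Republic
Cyprus	Cyprus
Netherlands	Netherlands
The Netherlands	Netherlands
Switzerland	Switzerland
Turkey	Turkey
Turkiye	Turkey
Egypt	Egypt
Saudi Arabia	Saudi Arabia
Brazil	Brazil
Poland	Poland
Norway	Norway
Denmark	Denmark
Austria	Austria
Finland	Finland
Greece	Greece
Portugal	Portugal
Russia	Russia
Russian Federation	Russia
Singapore	Singapore
Taiwan	Taiwan
Thailand	Thailand
Vietnam	Vietnam
Viet Nam	Vietnam
Israel	Israel
Belgium	Belgium
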